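"""End-to-end pipeline orchestration.

Runs simulate -> mosaic/dark frames -> demosaic -> dark-correct -> ROI
spectra -> outlier QC -> SPXY split -> model training -> evaluation ->
Grad-CAM -> classification map from a single flat configuration, writing
every stage artifact plus a manifest (sha256 per artifact) into a run
directory.  ``resume=True`` skips stages whose outputs already exist, unless
an upstream stage was re-executed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, interpret, models, msfa_cube, outlier_qc, spxy_split, synthetic_data
from .synthetic_data import SceneSpec, SpectrumModel

log = logging.getLogger("fluorocold")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat run configuration; defaults mirror the study's stated settings."""

    seed: int = 0
    out_dir: str = "runs/default"
    # generator
    n_pots: int = 120                 # pots per class; 3 leaf ROIs each
    scene_height: int = 60
    scene_width: int = 100
    saturation_fraction: float = 0.002
    sensor_gain: float = 4000.0       # intensity units -> sensor counts
    # demosaicing
    pattern: int = 5
    offset_x: int = 0
    offset_y: int = 3
    # QC / split
    qc_components: int = 2
    qc_ksd: float = 2.5
    split_ratio: float = 0.7
    stratified_split: bool = False
    # modeling
    model_kinds: tuple[str, ...] = ("lda", "qda", "gsvm", "deep")
    gsvm_gamma: float = 6.98
    gsvm_C: float = 17.66
    cv_folds: int = 10
    deep_max_epochs: int = 500
    deep_batch: int = 8
    deep_lr: float = 3e-4
    # interpretation
    gradcam_alpha: float = 0.05
    map_background_floor: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "model_kinds" in data:
            data["model_kinds"] = tuple(data["model_kinds"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["model_kinds"] = list(data["model_kinds"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _leaf_triangles(rng, height, width, n):
    """Small triangular 'leaves' placed in disjoint grid cells (no overlap)."""
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    ch, cw = height / rows, width / cols
    polys = []
    for k in range(n):
        r0 = (k // cols) * ch + 1
        c0 = (k % cols) * cw + 1
        dr, dc = ch - 3, cw - 3
        polys.append(np.array([
            [r0 + rng.uniform(0, 0.2 * dr), c0 + rng.uniform(0, 0.2 * dc)],
            [r0 + dr, c0 + rng.uniform(0, 0.5 * dc)],
            [r0 + rng.uniform(0, 0.5 * dr), c0 + dc],
        ]))
    return polys


def run_pipeline(cfg: RunConfig, resume: bool = False) -> Path:
    """Execute every stage; returns the run directory.

    Stage artifacts: spectra CSVs, QC report, split id lists, per-model
    metrics JSON, confusion CSVs, Grad-CAM CSV, classification-map CSV/PNG,
    mosaic TIFFs, ENVI cubes, and ``manifest.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest: dict[str, dict] = {}
    ran: set[str] = set()

    def stage(name: str, outputs: list[Path], fn) -> None:
        deps_reran = bool(ran)  # conservative: any earlier stage re-ran
        if resume and not deps_reran and all(p.exists() for p in outputs):
            log.info("stage %s: outputs present, skipped", name)
        else:
            try:
                fn()
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
            ran.add(name)
        manifest[name] = {str(p.relative_to(out)): _sha256(p) for p in outputs if p.exists()}

    model = SpectrumModel(seed=cfg.seed)
    rng = np.random.default_rng((cfg.seed, 10))
    wl = model.wavelengths

    # --- stage: scene simulation + imaging (one demonstration scene) ------
    scene_paths = [out / "scene_raw.tif", out / "scene_dark.tif", out / "scene_labels.csv"]

    def simulate_scene():
        # two well-separated stress levels, three leaves each
        triangles = _leaf_triangles(rng, cfg.scene_height, cfg.scene_width, 6)
        polys = [(tri, label) for tri, label in zip(triangles, (0, 0, 0, 2, 2, 2))]
        spec = SceneSpec(cfg.scene_height, cfg.scene_width, polys,
                         saturation_fraction=cfg.saturation_fraction)
        cube, labels = synthetic_data.render_scene(spec, model)
        dark = synthetic_data.dark_frame(
            cfg.offset_y + cfg.scene_height * cfg.pattern,
            cfg.offset_x + cfg.scene_width * cfg.pattern, seed=cfg.seed)
        frame = synthetic_data.mosaic(cube, cfg.pattern, (cfg.offset_x, cfg.offset_y))
        raw = np.clip(frame.values * cfg.sensor_gain + dark.values, 0, 2**16 - 1)
        msfa_cube.write_mosaic_tiff(scene_paths[0], msfa_cube.MosaicFrame(raw))
        msfa_cube.write_mosaic_tiff(scene_paths[1], dark)
        pd.DataFrame(labels).to_csv(scene_paths[2], index=False)

    stage("simulate_scene", scene_paths, simulate_scene)

    # --- stage: demosaic + dark-correct -----------------------------------
    cube_paths = [out / "scene_corrected.bsq", out / "scene_corrected.hdr"]

    def demosaic_stage():
        raw = msfa_cube.demosaic(msfa_cube.read_mosaic_tiff(scene_paths[0]),
                                 cfg.pattern, cfg.offset_x, cfg.offset_y, wavelengths=wl)
        dark = msfa_cube.demosaic(msfa_cube.read_mosaic_tiff(scene_paths[1]),
                                  cfg.pattern, cfg.offset_x, cfg.offset_y,
                                  wavelengths=wl, kind="dark")
        corrected = msfa_cube.dark_correct(raw, dark)
        corrected.values /= cfg.sensor_gain  # back to generator intensity units
        msfa_cube.write_envi(out / "scene_corrected", corrected)

    stage("demosaic", cube_paths, demosaic_stage)

    # --- stage: spectra dataset (pot-level, emulating leaf-ROI averaging) --
    spectra_path = out / "spectra.csv"

    def make_spectra():
        # three leaf ROIs per pot averaged into one representative spectrum
        leaves = synthetic_data.sample_spectra(model, n_per_class=3 * cfg.n_pots)
        pots, labels = [], []
        for c in (0, 1, 2):
            leaf_x = leaves.X[leaves.y == c]
            for i in range(cfg.n_pots):
                pots.append(msfa_cube.pot_spectrum(leaf_x[3 * i : 3 * i + 3]))
                labels.append(c)
        # a few corrupted spectra (partial saturation / acquisition errors)
        # enter the table before QC: large displacements in random directions
        n_bad = max(2, int(0.02 * len(pots)))
        bad_rows = rng.choice(len(pots), size=n_bad, replace=False)
        X = np.asarray(pots)
        u = rng.normal(size=(n_bad, X.shape[1]))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        X[bad_rows] = np.clip(X[bad_rows] + 30.0 * u, 0, 2**16 - 1)
        ds = synthetic_data.SpectralDataset(X, np.asarray(labels), wavelengths=wl)
        ds.to_frame().to_csv(spectra_path, index=False)

    stage("extract_spectra", [spectra_path], make_spectra)

    # --- stage: outlier QC -------------------------------------------------
    qc_paths = [out / "spectra_clean.csv", out / "qc_report.csv"]

    def qc_stage():
        ds = synthetic_data.SpectralDataset.from_frame(pd.read_csv(spectra_path))
        clean, report = outlier_qc.remove_outliers(ds, k=cfg.qc_components, k_sd=cfg.qc_ksd)
        clean.to_frame().to_csv(qc_paths[0], index=False)
        pd.DataFrame({"index": np.arange(len(ds)), "spe": report.spe,
                      "flagged": report.mask}).to_csv(qc_paths[1], index=False)
        for c, n in sorted(report.removed_per_class.items()):
            log.info("qc: class %d -> removed %d", c, n)
        log.info("qc: %d spectra in, %d removed, %d retained",
                 len(ds), report.n_removed, len(clean))

    stage("outlier_qc", qc_paths, qc_stage)

    # --- stage: SPXY split -------------------------------------------------
    split_paths = [out / "calibration.csv", out / "prediction.csv", out / "split_summary.json"]

    def split_stage():
        ds = synthetic_data.SpectralDataset.from_frame(pd.read_csv(qc_paths[0]))
        select = spxy_split.spxy_select_stratified if cfg.stratified_split \
            else spxy_split.spxy_select
        res = select(ds, ratio=cfg.split_ratio)
        cal = ds.subset(np.isin(ds.ids, res.calibration_ids))
        pred = ds.subset(np.isin(ds.ids, res.prediction_ids))
        cal.to_frame().to_csv(split_paths[0], index=False)
        pred.to_frame().to_csv(split_paths[1], index=False)
        summary = {
            "ratio": cfg.split_ratio,
            "calibration_per_class": {int(c): int((cal.y == c).sum()) for c in (0, 1, 2)},
            "prediction_per_class": {int(c): int((pred.y == c).sum()) for c in (0, 1, 2)},
        }
        split_paths[2].write_text(json.dumps(summary, indent=2))

    stage("spxy_split", split_paths, split_stage)

    # --- stage: training + evaluation --------------------------------------
    metrics_path = out / "metrics.json"
    hsd_path = out / "tukey_hsd.csv"

    def modeling_stage():
        cal = synthetic_data.SpectralDataset.from_frame(pd.read_csv(split_paths[0]))
        pred = synthetic_data.SpectralDataset.from_frame(pd.read_csv(split_paths[1]))
        train_cfg = models.TrainConfig(
            max_epochs=cfg.deep_max_epochs, batch=cfg.deep_batch, lr=cfg.deep_lr,
            # patience windows shrink with a reduced epoch budget
            early_stop_patience=min(50, max(1, cfg.deep_max_epochs - 1)),
            lr_patience=min(25, max(1, cfg.deep_max_epochs // 2)),
        )

        def factory(kind):
            if kind == "deep":
                return lambda ds: models.train_deep(ds, cfg=train_cfg)
            if kind == "gsvm":
                return lambda ds: models.train_classical(
                    "gsvm", ds, gamma=cfg.gsvm_gamma, C=cfg.gsvm_C)
            return lambda ds: models.train_classical(kind, ds)

        all_metrics, fold_accs = {}, {}
        for kind in cfg.model_kinds:
            fit = factory(kind)
            trained = fit(cal)
            trained.save(out / f"model_{kind}.pkl")
            y_hat = models.predict(trained, pred.X)
            cm = evaluation.confusion(pred.y, y_hat)
            rep = evaluation.metrics(cm)
            rep.auc = evaluation.roc_auc(pred.y, models.predict_proba(trained, pred.X))
            cv = evaluation.kfold_cv(fit, cal, k=cfg.cv_folds, seed=cfg.seed)
            fold_accs[kind] = cv.fold_accuracies
            pd.DataFrame(cm.counts).to_csv(out / f"confusion_{kind}.csv", index=False)
            pd.DataFrame(cm.normalized()).to_csv(
                out / f"confusion_{kind}_normalized.csv", index=False)
            all_metrics[kind] = {
                "prediction": {k: getattr(rep, k) for k in
                               ("accuracy", "precision", "recall", "f1")},
                "auc": rep.auc,
                "cross_validation": cv.summary(),
            }
            log.info("model %s: prediction accuracy %.1f", kind, rep.accuracy)
        metrics_path.write_text(json.dumps(all_metrics, indent=2))
        if len(fold_accs) >= 2:
            evaluation.tukey_hsd(fold_accs).to_csv(hsd_path, index=False)

    stage("modeling", [metrics_path, hsd_path], modeling_stage)

    # --- stage: Grad-CAM + classification map ------------------------------
    interp_paths = [out / "gradcam.csv", out / "classification_map.csv",
                    out / "classification_map.png"]

    def interpret_stage():
        # Grad-CAM needs the deep model's conv features; maps fall back to
        # the first trained classifier if the deep model was not requested
        if "deep" in cfg.model_kinds:
            cal = synthetic_data.SpectralDataset.from_frame(pd.read_csv(split_paths[0]))
            deep = models.TrainedModel.load(out / "model_deep.pkl")
            profile = interpret.gradcam_profile(deep, cal, alpha=cfg.gradcam_alpha)
            df = pd.DataFrame(profile.class_means.T, columns=["class0", "class1", "class2"])
            df.insert(0, "wavelength_nm", wl)
            df["pvalue"] = profile.pvalues
            df["significant"] = np.isin(np.arange(len(wl)), profile.significant)
            df.to_csv(interp_paths[0], index=False)
            mapper = deep
        else:
            mapper = models.TrainedModel.load(out / f"model_{cfg.model_kinds[0]}.pkl")

        cube = msfa_cube.read_envi(out / "scene_corrected", kind="corrected")
        cmap = interpret.classify_map(cube, mapper, cfg.map_background_floor)
        pd.DataFrame(cmap.labels).to_csv(interp_paths[1], index=False)
        _save_map_png(interp_paths[2], cmap.labels)

    stage("interpret", interp_paths if "deep" in cfg.model_kinds else interp_paths[1:],
          interpret_stage)

    (out / "manifest.json").write_text(json.dumps(
        {"seed": cfg.seed, "stages": manifest}, indent=2))
    return out


def _save_map_png(path, labels: np.ndarray) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    cmap = ListedColormap(["#222222", "#2ca02c", "#ff7f0e", "#d62728"])
    norm = BoundaryNorm([-1.5, -0.5, 0.5, 1.5, 2.5], cmap.N)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(labels, cmap=cmap, norm=norm, interpolation="nearest")
    fig.colorbar(im, ax=ax, ticks=[-1, 0, 1, 2],
                 label="class (-1 background, 0 normal, 1 moderate, 2 severe)")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
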