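"""Synthetic chlorophyll-fluorescence data generator.

Emulates the statistical structure of UV-excited (405 nm) chlorophyll
fluorescence measurements of plants under three cold-stress levels, so that
every downstream stage — demosaicing, QC, splitting, modeling, attribution,
mapping — can be exercised without the original camera data.

The emission template is the sum of two Gaussian peaks at the canonical
chlorophyll emission maxima F685 and F740, evaluated at 25 band centers
spanning 603–870 nm.  Cold stress suppresses overall fluorescence yield, so
the three classes share the template shape but carry strictly decreasing
amplitudes: class 0 (normal) > class 1 (moderate) > class 2 (severe).
Per-sample variability is a multiplicative log-normal factor (illumination
non-uniformity, leaf geometry); sensor noise is additive Gaussian per band;
saturated pixels emulate sensor clipping artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msfa_cube import (
    Hypercube,
    MosaicFrame,
    N_BANDS,
    PATTERN,
    _check_layout,
    default_layout,
    points_in_polygon,
)

__all__ = [
    "SpectrumModel",
    "SceneSpec",
    "SpectralDataset",
    "default_wavelengths",
    "class_template",
    "sample_spectra",
    "single_band_dataset",
    "render_scene",
    "mosaic",
    "dark_frame",
]

WAVELENGTH_MIN = 603.0
WAVELENGTH_MAX = 870.0


def default_wavelengths(n: int = N_BANDS) -> np.ndarray:
    """25 evenly spaced band centers over 603–870 nm (step 11.125 nm).

    The camera's true band centers are not public; only the spectral range
    is.  An explicit center list can be passed to :class:`SpectrumModel`
    instead.
    """
    return np.linspace(WAVELENGTH_MIN, WAVELENGTH_MAX, n)


def nearest_band(wavelengths: np.ndarray, nominal_nm: float) -> tuple[int, float]:
    """Map a named wavelength to the nearest grid band.

    Returns ``(band_index, mismatch_nm)``; the mismatch flags named bands
    (e.g. 639, 679, 693, 717, 757 nm) that do not fall exactly on the grid.
    """
    idx = int(np.argmin(np.abs(np.asarray(wavelengths) - nominal_nm)))
    return idx, float(wavelengths[idx] - nominal_nm)


@dataclass
class SpectrumModel:
    """Generative model of three-class fluorescence emission spectra.

    Parameters
    ----------
    wavelengths : band centers in nm, strictly increasing, 603..870.
    class_amplitudes : per-class emission scale, strictly decreasing
        (normal > moderate > severe), arbitrary intensity units.
    peak_centers, peak_widths : Gaussian emission peak positions and scales
        in nm (defaults: chlorophyll F685/F740, widths 18/35 nm).
    noise_sd : additive per-band Gaussian noise scale.
    sample_cv : coefficient of variation of the per-sample multiplicative
        log-normal factor (mean 1).
    seed : master seed for all stochastic draws.
    """

    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    class_amplitudes: tuple[float, float, float] = (3.0, 2.2, 1.5)
    peak_centers: tuple[float, float] = (685.0, 740.0)
    peak_widths: tuple[float, float] = (18.0, 35.0)
    noise_sd: float = 0.15
    sample_cv: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (
            self.wavelengths[0] == WAVELENGTH_MIN and self.wavelengths[-1] == WAVELENGTH_MAX
        ):
            raise ValueError("wavelengths must span 603..870 nm")
        a = self.class_amplitudes
        if not (a[0] > a[1] > a[2] > 0):
            raise ValueError("class amplitudes must be strictly decreasing and positive")
        if min(self.peak_widths) <= 0 or self.noise_sd < 0 or self.sample_cv < 0:
            raise ValueError("widths must be > 0 and noise scales >= 0")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def class_template(model: SpectrumModel, label: int) -> np.ndarray:
    """Noiseless emission template of one stress class.

    Sum of the two Gaussian peaks at the band centers, scaled by the class
    amplitude.  Deterministic; the basis of every sampled spectrum.
    """
    if label not in (0, 1, 2):
        raise ValueError(f"unknown class label {label!r}")
    wl = model.wavelengths
    shape = np.zeros_like(wl)
    for center, width in zip(model.peak_centers, model.peak_widths):
        shape += np.exp(-0.5 * ((wl - center) / width) ** 2)
    return model.class_amplitudes[label] * shape


@dataclass
class SpectralDataset:
    """N labeled spectra: ``X`` is N x bands, ``y`` in {0, 1, 2}."""

    X: np.ndarray
    y: np.ndarray
    ids: np.ndarray | None = None
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D with one label per row")
        if np.isnan(self.X).any():
            raise ValueError("missing values in X")
        if self.ids is None:
            self.ids = np.arange(len(self.y))
        self.ids = np.asarray(self.ids)

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, index: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(self.X[index], self.y[index], self.ids[index], self.wavelengths)

    def to_frame(self):
        import pandas as pd

        cols = [f"band_{w:g}" for w in self.wavelengths]
        df = pd.DataFrame(self.X, columns=cols)
        df["label"] = self.y
        return df

    @classmethod
    def from_frame(cls, df) -> "SpectralDataset":
        bands = [c for c in df.columns if c.startswith("band_")]
        wl = np.array([float(c.split("_", 1)[1]) for c in bands])
        return cls(df[bands].to_numpy(float), df["label"].to_numpy(int), wavelengths=wl)


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Log-normal multipliers with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


def sample_spectra(model: SpectrumModel, n_per_class: int) -> SpectralDataset:
    """Draw ``n_per_class`` spectra per stress class.

    spectrum = template * LogNormal(mean 1, CV = sample_cv)  (per sample)
               + Normal(0, noise_sd)                         (per band)
    clipped at 0.  Reproducible under the model's seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = model.rng(salt=1)
    blocks, labels = [], []
    for label in (0, 1, 2):
        template = class_template(model, label)
        factors = _lognormal_factors(rng, n_per_class, model.sample_cv)
        noise = rng.normal(0.0, model.noise_sd, size=(n_per_class, template.size)) \
            if model.noise_sd > 0 else 0.0
        blocks.append(np.clip(factors[:, None] * template[None, :] + noise, 0, None))
        labels.append(np.full(n_per_class, label))
    return SpectralDataset(np.vstack(blocks), np.concatenate(labels), wavelengths=model.wavelengths)


def single_band_dataset(
    n_per_class: int,
    informative_band: int = 12,
    class_levels: tuple[float, float, float] = (3.0, 2.0, 1.0),
    noise_sd: float = 0.3,
    seed: int = 0,
    n_bands: int = N_BANDS,
) -> SpectralDataset:
    """Dataset where class identity lives in one band only.

    All bands are i.i.d. noise except ``informative_band``, which carries a
    class-dependent level plus the same noise.  Used to probe whether a
    trained model's wavelength attribution recovers the injected band.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(1.0, noise_sd, size=(3 * n_per_class, n_bands))
    y = np.repeat([0, 1, 2], n_per_class)
    for label, level in enumerate(class_levels):
        rows = y == label
        X[rows, informative_band] = level + rng.normal(0, noise_sd, rows.sum())
    return SpectralDataset(np.clip(X, 0, None), y)


@dataclass
class SceneSpec:
    """Layout of a synthetic leaf scene.

    ``leaf_polygons`` is a list of ``(vertices, class_label)`` pairs with
    vertices in (row, col) pixel coordinates inside the frame.  Background
    pixels carry ``background_level`` at all bands.  ``saturation_fraction``
    of the pixels is forced to the sensor maximum before mosaicking.
    """

    height: int
    width: int
    leaf_polygons: list[tuple[np.ndarray, int]] = field(default_factory=list)
    background_level: float = 0.02
    saturation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.saturation_fraction <= 1:
            raise ValueError("saturation_fraction must lie in [0, 1]")
        for vertices, label in self.leaf_polygons:
            v = np.asarray(vertices, dtype=float)
            if (v[:, 0] < 0).any() or (v[:, 0] > self.height).any() \
                    or (v[:, 1] < 0).any() or (v[:, 1] > self.width).any():
                raise ValueError("polygon vertices must lie within the frame")
            if label not in (0, 1, 2):
                raise ValueError(f"unknown class label {label!r}")


def render_scene(
    spec: SceneSpec, model: SpectrumModel, sensor_max: float = 2**16 - 1
) -> tuple[Hypercube, np.ndarray]:
    """Render a labeled scene into a ground-truth hypercube.

    Every pixel inside a leaf polygon receives an independent sampled
    spectrum of that polygon's class; background pixels are flat at
    ``background_level``.  Returns ``(cube, label_image)`` with label -1 for
    background.  Overlapping polygons are rejected: the label would be
    ambiguous.
    """
    rr, cc = np.meshgrid(np.arange(spec.height), np.arange(spec.width), indexing="ij")
    centers = np.stack([rr.ravel(), cc.ravel()], axis=1)
    labels = np.full(spec.height * spec.width, -1, dtype=int)
    claimed = np.zeros(labels.size, dtype=bool)
    masks = []
    for vertices, label in spec.leaf_polygons:
        inside = points_in_polygon(centers, np.asarray(vertices, dtype=float))
        if (claimed & inside).any():
            raise ValueError("overlapping leaf polygons: pixel label is ambiguous")
        claimed |= inside
        masks.append((inside, label))
        labels[inside] = label

    n_bands = model.wavelengths.size
    cube = np.full((labels.size, n_bands), spec.background_level, dtype=float)
    rng = model.rng(salt=2)
    for inside, label in masks:
        n = int(inside.sum())
        if n == 0:
            continue
        template = class_template(model, label)
        factors = _lognormal_factors(rng, n, model.sample_cv)
        noise = rng.normal(0.0, model.noise_sd, size=(n, n_bands)) if model.noise_sd > 0 else 0.0
        cube[inside] = np.clip(factors[:, None] * template[None, :] + noise, 0, None)

    if spec.saturation_fraction > 0:
        n_sat = int(round(spec.saturation_fraction * labels.size))
        sat = rng.choice(labels.size, size=n_sat, replace=False)
        cube[sat] = sensor_max

    cube = cube.reshape(spec.height, spec.width, n_bands)
    return (
        Hypercube(cube, model.wavelengths, kind="raw"),
        labels.reshape(spec.height, spec.width),
    )


def mosaic(
    cube: Hypercube,
    pattern: int = PATTERN,
    offsets: tuple[int, int] = (0, 0),
    layout: np.ndarray | None = None,
    bit_depth: int = 16,
) -> MosaicFrame:
    """Interleave a hypercube into a single mosaiced frame.

    Exact inverse of demosaicing for the same pattern/offsets/layout: frame
    value at ``(offset_y + pattern*i + r_b, offset_x + pattern*j + c_b)``
    is ``cube[i, j, b]``.  The offset margins (rows/cols before the first
    full tile) are zero-filled.
    """
    offset_x, offset_y = offsets
    if cube.n_bands != pattern * pattern:
        raise ValueError(f"cube must have {pattern * pattern} bands")
    layout = default_layout(pattern) if layout is None else _check_layout(layout, pattern)
    rows, cols, _ = cube.shape
    frame = np.zeros((offset_y + rows * pattern, offset_x + cols * pattern))
    for b, (r, c) in enumerate(layout):
        frame[offset_y + r :: pattern, offset_x + c :: pattern] = cube.values[:, :, b]
    return MosaicFrame(np.minimum(frame, 2**bit_depth - 1), bit_depth=bit_depth)


def dark_frame(
    height: int, width: int, offset_level: float = 96.0, read_noise_sd: float = 4.0,
    seed: int = 0, bit_depth: int = 16,
) -> MosaicFrame:
    """Dark-reference mosaic frame: sensor offset plus read noise."""
    rng = np.random.default_rng((seed, 3))
    values = np.clip(rng.normal(offset_level, read_noise_sd, size=(height, width)), 0, None)
    return MosaicFrame(values, bit_depth=bit_depth)
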