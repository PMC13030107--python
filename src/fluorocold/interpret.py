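"""Model interpretation: 1-D Grad-CAM band attribution and classification maps.

Grad-CAM for spectra: for a chosen class, the gradient of that class's logit
with respect to the last convolutional feature map (the batch-normalized,
ReLU-activated output of the second 1-D convolution, length 25 x 128
channels) is averaged over the 25 sequence positions to give one weight per
channel; the relevance score at each wavelength position is the ReLU of the
channel-weighted sum of the feature map.  The sequence length already equals
the band count, so no upsampling is needed.  Per-band one-way ANOVA across
the three class groups of per-sample scores (computed on correctly predicted
samples) screens for wavelengths with significant class-dependent
attribution differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import TrainedModel, predict
from .msfa_cube import Hypercube

__all__ = [
    "GradCamProfile", "ClassificationMap",
    "grad_cam_1d", "gradcam_profile", "gradcam_anova", "classify_map",
]

# layer indices in the deep model's Sequential stack
_POST_CONV_RELU = 4  # encoder GRU index; its input is the conv-block activation


@dataclass
class GradCamProfile:
    scores: np.ndarray        # n_samples x bands, per-sample relevance
    labels: np.ndarray        # class of each profiled sample
    class_means: np.ndarray   # 3 x bands
    pvalues: np.ndarray | None = None
    significant: np.ndarray | None = None


@dataclass
class ClassificationMap:
    labels: np.ndarray  # rows x cols in {-1, 0, 1, 2}; -1 = background

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("map must be 2-D")


def _conv_block_forward(net, x: np.ndarray) -> np.ndarray:
    a = x
    for layer in net.layers[:_POST_CONV_RELU]:
        a = layer.forward(a, training=False)
    return a


def grad_cam_1d(model: TrainedModel, spectra: np.ndarray, target_class: int) -> np.ndarray:
    """Per-band Grad-CAM relevance of ``target_class`` for one or more spectra.

    Accepts a single 25-vector or an ``(n, 25)`` matrix; returns scores of
    matching shape.  Only defined for the deep model (it is the only one with
    a convolutional feature map).
    """
    if model.kind != "deep":
        raise ValueError("Grad-CAM requires the deep model")
    if target_class not in (0, 1, 2):
        raise ValueError(f"unknown class {target_class!r}")
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    single = np.asarray(spectra).ndim == 1
    net = model.estimator
    x = X[:, :, None]

    A = _conv_block_forward(net, x)          # (n, 25, filters)
    out = A
    for layer in net.layers[_POST_CONV_RELU:]:
        out = layer.forward(out, training=False)
    dlogits = np.zeros_like(out)
    dlogits[:, target_class] = 1.0           # gradient of the chosen logit
    dA = net.backward(dlogits, until=_POST_CONV_RELU)  # (n, 25, filters)

    weights = dA.mean(axis=1)                # channel weights, per sample
    cam = np.maximum((A * weights[:, None, :]).sum(axis=2), 0.0)
    return cam[0] if single else cam


def gradcam_profile(model: TrainedModel, dataset, alpha: float = 0.05,
                    bonferroni: bool = False) -> GradCamProfile:
    """Grad-CAM scores of correctly predicted samples, plus ANOVA screening.

    Each correctly predicted sample is attributed against its own (true)
    class; per-band one-way ANOVA across the three class groups flags
    wavelengths whose attribution differs by class at ``p < alpha``.
    """
    y_pred = predict(model, dataset.X)
    correct = y_pred == dataset.y
    if correct.sum() == 0:
        raise ValueError("no correctly predicted samples to profile")
    X, y = dataset.X[correct], dataset.y[correct]
    scores = np.empty((len(X), X.shape[1]))
    for c in np.unique(y):
        rows = y == c
        scores[rows] = grad_cam_1d(model, X[rows], int(c))
    class_means = np.stack([
        scores[y == c].mean(axis=0) if (y == c).any() else np.full(X.shape[1], np.nan)
        for c in (0, 1, 2)
    ])
    pvalues, significant = gradcam_anova(scores, y, alpha=alpha, bonferroni=bonferroni)
    return GradCamProfile(scores=scores, labels=y, class_means=class_means,
                          pvalues=pvalues, significant=significant)


def gradcam_anova(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05,
                  bonferroni: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-band one-way ANOVA of per-sample scores across class groups.

    Returns ``(pvalues, significant_band_indices)``.  A band where every
    group is constant with equal means carries no evidence and gets p = 1.
    """
    labels = np.asarray(labels)
    groups_idx = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    if len(groups_idx) < 2 or any(len(g) < 2 for g in groups_idx):
        raise ValueError("need >= 2 classes with >= 2 samples each")
    n_bands = scores.shape[1]
    pvalues = np.ones(n_bands)
    for b in range(n_bands):
        groups = [scores[g, b] for g in groups_idx]
        if all(np.ptp(g) == 0 for g in groups) and np.ptp([g[0] for g in groups]) == 0:
            pvalues[b] = 1.0
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            pvalues[b] = stats.f_oneway(*groups).pvalue
    cut = alpha / n_bands if bonferroni else alpha
    return pvalues, np.flatnonzero(pvalues < cut)


def classify_map(cube: Hypercube, model: TrainedModel,
                 background_floor: float = 0.0) -> ClassificationMap:
    """Pixel-wise classification of a corrected hypercube.

    Every pixel whose mean intensity is at or above ``background_floor`` is
    scored by the model (argmax class); pixels below the floor are labeled -1.
    The default floor of 0 classifies every pixel (no masking).
    """
    if cube.n_bands != model.n_bands:
        raise ValueError(f"cube has {cube.n_bands} bands, model expects {model.n_bands}")
    rows, cols, _ = cube.shape
    flat = cube.values.reshape(-1, cube.n_bands)
    keep = flat.mean(axis=1) >= background_floor
    labels = np.full(len(flat), -1, dtype=int)
    if keep.any():
        labels[keep] = predict(model, flat[keep])
    return ClassificationMap(labels.reshape(rows, cols))
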