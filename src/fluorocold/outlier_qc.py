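"""PCA residual-distance (SPE / DModX) outlier screening.

Atypical spectra — saturated pixels, acquisition glitches — sit far from the
low-dimensional subspace that captures most spectral variance.  A PCA model
with K components (default 2) is fitted to the spectra; each sample's squared
prediction error (SPE, also called distance-to-model / DModX) is the squared
Euclidean norm of its residual after projection onto the component subspace.
Samples whose SPE exceeds mean + k_sd * SD (default 2.5 standard deviations;
SPE is nonnegative, so the lower bound of a symmetric cut can never flag
anything and an upper one-sided cut is applied) are removed before modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["PcaModel", "OutlierReport", "fit_pca", "spe", "flag_outliers", "remove_outliers"]


@dataclass
class PcaModel:
    mean: np.ndarray
    loadings: np.ndarray  # bands x K, orthonormal columns
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.loadings.shape[1]), atol=1e-8):
            raise ValueError("loadings columns must be orthonormal")
        r = self.explained_variance_ratio
        if (r < 0).any() or (r > 1).any() or np.any(np.diff(r) > 1e-12):
            raise ValueError("explained variance ratios must be non-increasing in [0, 1]")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class OutlierReport:
    spe: np.ndarray
    threshold: float
    mask: np.ndarray  # True = outlier
    removed_per_class: dict[int, int]

    def __post_init__(self) -> None:
        if not np.array_equal(self.mask, self.spe > self.threshold):
            raise ValueError("mask inconsistent with spe > threshold")
        if sum(self.removed_per_class.values()) != int(self.mask.sum()):
            raise ValueError("per-class counts do not sum to total removed")

    @property
    def n_removed(self) -> int:
        return int(self.mask.sum())


def fit_pca(X: np.ndarray, k: int = 2) -> PcaModel:
    """Mean-centered PCA; loadings are the top-k covariance eigenvectors."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if not n > k >= 1:
        raise ValueError("need N > k >= 1")
    if np.allclose(X, X[0]):
        raise ValueError("constant matrix has no variance to decompose")
    pca = PCA(n_components=k, svd_solver="full").fit(X)
    return PcaModel(
        mean=pca.mean_,
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def spe(X: np.ndarray, model: PcaModel) -> np.ndarray:
    """Squared prediction error of each sample w.r.t. the PCA subspace."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.mean.size:
        raise ValueError(f"band count {X.shape[1]} does not match model ({model.mean.size})")
    centered = X - model.mean
    residual = centered - (centered @ model.loadings) @ model.loadings.T
    return np.einsum("ij,ij->i", residual, residual)


def flag_outliers(
    spe_values: np.ndarray, k_sd: float = 2.5, labels: np.ndarray | None = None
) -> OutlierReport:
    """Flag samples whose SPE exceeds mean + k_sd * SD (ddof=1)."""
    s = np.asarray(spe_values, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 samples to estimate the SPE spread")
    sd = s.std(ddof=1)
    if sd == 0:
        warnings.warn("SPE has zero variance; no outliers flagged", stacklevel=2)
        threshold = float(s.mean())
        mask = np.zeros(len(s), dtype=bool)
    else:
        threshold = float(s.mean() + k_sd * sd)
        mask = s > threshold
    per_class: dict[int, int] = {}
    if labels is not None:
        labels = np.asarray(labels)
        per_class = {int(c): int(mask[labels == c].sum()) for c in np.unique(labels)}
    else:
        per_class = {-1: int(mask.sum())}
    return OutlierReport(spe=s, threshold=threshold, mask=mask, removed_per_class=per_class)


def remove_outliers(dataset, k: int = 2, k_sd: float = 2.5):
    """Fit PCA, score SPE, drop flagged spectra. Returns (clean, report)."""
    model = fit_pca(dataset.X, k=k)
    report = flag_outliers(spe(dataset.X, model), k_sd=k_sd, labels=dataset.y)
    return dataset.subset(~report.mask), report
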