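"""SPXY calibration/prediction set partitioning.

Sample-set partitioning based on joint X–Y distances: the pairwise distance

    D_SPXY(i, j) = D_x(i, j) / max D_x + D_y(i, j) / max D_y

combines the Euclidean distance between spectra (D_x) and between reference
labels (D_y = |y_i - y_j|), each self-normalized by its maximum so both
contribute on a common [0, 1] scale (hence 0 <= D_SPXY <= 2).  Selection is
the standard greedy max–min construction: seed with the mutually farthest
pair, then repeatedly add the sample whose minimum distance to the selected
set is largest, until the calibration set reaches round(ratio * N).  The
remainder is the prediction set.  Selection is global (not class-stratified),
so per-class ratios can deviate from the target; a stratified variant exists
for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["SplitResult", "pairwise_distances", "spxy_select", "random_split"]


@dataclass
class SplitResult:
    calibration_ids: np.ndarray
    prediction_ids: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.prediction_ids):
            raise ValueError("calibration and prediction sets overlap")


def _half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def pairwise_distances(dataset) -> np.ndarray:
    """N x N matrix of D_SPXY distances (symmetric, zero diagonal).

    If all spectra are identical (max D_x = 0) or all labels equal
    (max D_y = 0), the degenerate term is dropped with a warning rather than
    dividing by zero.
    """
    X = np.asarray(dataset.X, dtype=float)
    y = np.asarray(dataset.y, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 samples")
    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    d = np.zeros_like(dx)
    if dx.max() > 0:
        d += dx / dx.max()
    else:
        warnings.warn("all spectra identical; X-distance term dropped", stacklevel=2)
    if dy.max() > 0:
        d += dy / dy.max()
    else:
        warnings.warn("all labels identical; Y-distance term dropped", stacklevel=2)
    return d


def spxy_select(dataset, ratio: float = 0.7) -> SplitResult:
    """Greedy max–min SPXY selection of the calibration set.

    Deterministic: ties in the max–min criterion (and in the seeding pair)
    are broken by the smallest sample id.
    """
    n = len(dataset.y)
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n_cal = _half_up(ratio * n)
    if n_cal >= n:
        raise ValueError(f"ratio {ratio} selects all {n} samples; prediction set empty")
    if n_cal < 2:
        n_cal = 2

    ids = np.asarray(dataset.ids)
    order = np.argsort(ids, kind="stable")  # id order for tie-breaking
    d = pairwise_distances(dataset)[np.ix_(order, order)]

    # seed: the mutually farthest pair; row-major argmax takes the
    # smallest-id pair on ties
    i0, j0 = np.unravel_index(int(np.argmax(d)), d.shape)
    selected = [min(i0, j0), max(i0, j0)]
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    # min distance of every sample to the selected set, kept incrementally
    dmin = np.minimum(d[:, selected[0]], d[:, selected[1]])
    dmin[in_set] = -np.inf

    while len(selected) < n_cal:
        pick = int(np.argmax(dmin))  # first (lowest id) on ties
        selected.append(pick)
        in_set[pick] = True
        dmin = np.minimum(dmin, d[:, pick])
        dmin[pick] = -np.inf

    cal = np.sort(ids[order][selected])
    pred = np.sort(ids[order][~in_set])
    return SplitResult(calibration_ids=cal, prediction_ids=pred, ratio=ratio)


def spxy_select_stratified(dataset, ratio: float = 0.7) -> SplitResult:
    """Per-class SPXY selection (off by default; comparison tool only)."""
    cal_parts, pred_parts = [], []
    for label in np.unique(dataset.y):
        idx = np.flatnonzero(dataset.y == label)
        sub = dataset.subset(idx)
        res = spxy_select(sub, ratio=ratio)
        cal_parts.append(res.calibration_ids)
        pred_parts.append(res.prediction_ids)
    return SplitResult(np.sort(np.concatenate(cal_parts)), np.sort(np.concatenate(pred_parts)), ratio)


def random_split(dataset, ratio: float = 0.7, seed: int = 0) -> SplitResult:
    """Seeded uniform random split (labeled alternative for tests)."""
    n = len(dataset.y)
    n_cal = _half_up(ratio * n)
    perm = np.random.default_rng(seed).permutation(n)
    ids = np.asarray(dataset.ids)
    return SplitResult(np.sort(ids[perm[:n_cal]]), np.sort(ids[perm[n_cal:]]), ratio)
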