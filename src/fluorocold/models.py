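"""Classifiers for three-class cold-stress discrimination from spectra.

Four models are provided:

* LDA and QDA at scikit-learn defaults;
* a Gaussian (RBF) SVM whose ``gamma``/``C`` pair is either supplied directly
  or tuned by a seeded genetic algorithm maximizing 5-fold CV accuracy;
* a sequence deep model that treats the 25-band spectrum as ordered data
  along wavelength: two 1-D convolutions (128 filters, kernel 2, stride 1,
  'same' padding, He-normal init; batch norm + ReLU after the second) feed a
  GRU encoder whose final 64-unit hidden state is repeated 25 times as the
  context sequence for a GRU decoder; the decoder's final state passes
  through a small MLP head into a 3-way softmax.

The deep model trains with Adam (categorical cross-entropy, batch 8, initial
learning rate 3e-4), early stopping on validation loss (min delta 1e-4,
patience 50, best weights restored) and plateau learning-rate halving
(patience 25), for at most 500 epochs, with a stratified 4:1
train/validation split.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from . import nn

__all__ = [
    "DeepModelConfig", "TrainConfig", "TrainedModel",
    "build_deep_model", "one_hot", "train_deep", "train_classical",
    "ga_optimize", "predict", "predict_proba",
]


@dataclass
class DeepModelConfig:
    input_len: int = 25
    conv_filters: int = 128
    kernel: int = 2
    gru_hidden: int = 64
    dense_units: tuple[int, int] = (64, 32)  # table variant: (64, 64)
    classes: int = 3
    relu_after_dense2: bool = False

    def __post_init__(self) -> None:
        sizes = (self.input_len, self.conv_filters, self.kernel,
                 self.gru_hidden, *self.dense_units, self.classes)
        if any(s <= 0 for s in sizes):
            raise ValueError("all layer sizes must be positive")


@dataclass
class TrainConfig:
    max_epochs: int = 500
    batch: int = 8
    lr: float = 3e-4
    early_stop_min_delta: float = 1e-4
    early_stop_patience: int = 50
    lr_factor: float = 0.5
    lr_patience: int = 25
    val_fraction: float = 0.2
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrainedModel:
    """Uniform wrapper around a fitted classifier.

    ``kind`` is one of lda/qda/gsvm/deep; ``estimator`` holds the sklearn
    estimator or the :class:`fluorocold.nn.Sequential` network;
    ``training_log`` (deep only) records per-epoch train/validation loss and
    accuracy.
    """

    kind: str
    estimator: object
    label_order: np.ndarray
    n_bands: int
    config: dict = field(default_factory=dict)
    training_log: list[dict] | None = None
    epochs_run: int | None = None

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def build_deep_model(
    cfg: DeepModelConfig, seed: int = 42
) -> tuple[nn.Sequential, list[tuple[str, tuple]]]:
    """Instantiate the CNN–GRU encoder–decoder and its layer-shape listing."""
    rng = np.random.default_rng(seed)
    L, F, H = cfg.input_len, cfg.conv_filters, cfg.gru_hidden
    d1, d2 = cfg.dense_units
    layers: list[nn.Layer] = [
        nn.Conv1D(1, F, cfg.kernel, rng),                 # Conv1D #1 (no activation)
        nn.Conv1D(F, F, cfg.kernel, rng),                 # Conv1D #2
        nn.BatchNorm(F),
        nn.ReLU(),
        nn.GRU(F, H, rng),                                # encoder -> final state
        nn.RepeatVector(L),                               # context sequence
        nn.GRU(H, H, rng),                                # decoder -> final state
        nn.Dense(H, d1, rng),
        nn.ReLU(),
        nn.Dense(d1, d2, rng),
    ]
    if cfg.relu_after_dense2:
        layers.append(nn.ReLU())
    layers.append(nn.Dense(d2, cfg.classes, rng))         # softmax in the loss
    model = nn.Sequential(layers)
    shapes = [
        ("Input spectra", (None, L, 1)),
        ("Conv1D #1", (None, L, F)),
        ("Conv1D #2 + BN + ReLU", (None, L, F)),
        ("Encoder—GRU", (None, H)),
        ("Context vector", (None, L, H)),
        ("Decoder—GRU", (None, H)),
        ("Dense #1 + ReLU", (None, d1)),
        ("Dense #2", (None, d2)),
        ("Softmax", (None, cfg.classes)),
    ]
    return model, shapes


def one_hot(labels: np.ndarray, classes: int = 3) -> np.ndarray:
    """Indicator matrix: row i has a single 1 in column ``labels[i]``."""
    labels = np.asarray(labels, dtype=int)
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= classes:
        raise ValueError(f"labels must lie in [0, {classes})")
    out = np.zeros((len(labels), classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def train_deep(
    dataset,
    model_cfg: DeepModelConfig | None = None,
    cfg: TrainConfig | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Train the deep model on a calibration dataset.

    The calibration set is split 4:1 into training and validation subsets by
    stratified sampling at the configured seed; early stopping monitors
    validation loss and restores the best weights.
    """
    model_cfg = model_cfg or DeepModelConfig()
    cfg = cfg or TrainConfig()
    X, y = np.asarray(dataset.X, float), np.asarray(dataset.y, int)
    classes = np.unique(y)
    if len(classes) < model_cfg.classes:
        raise ValueError(f"calibration set must contain all {model_cfg.classes} classes")

    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=cfg.val_fraction, stratify=y, random_state=cfg.seed
    )
    net, _ = build_deep_model(model_cfg, seed=cfg.seed)
    opt = nn.Adam(net, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)

    Y_tr = one_hot(y_tr, model_cfg.classes)
    Y_val = one_hot(y_val, model_cfg.classes)
    xt = X_tr[:, :, None]
    xv = X_val[:, :, None]

    best_val = np.inf
    best_weights = net.get_weights()
    wait_stop = wait_lr = 0
    log: list[dict] = []
    epochs_run = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(xt))
        train_loss = 0.0
        for start in range(0, len(xt), cfg.batch):
            idx = order[start : start + cfg.batch]
            net.zero_grad()
            logits = net.forward(xt[idx], training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, Y_tr[idx])
            net.backward(dlogits)
            opt.step()
            train_loss += loss * len(idx)
        train_loss /= len(xt)

        logits_tr = net.forward(xt, training=False)
        logits_val = net.forward(xv, training=False)
        val_loss, _ = nn.softmax_cross_entropy(logits_val, Y_val)
        log.append({
            "epoch": epoch + 1,
            "loss": train_loss,
            "accuracy": float((logits_tr.argmax(1) == y_tr).mean()),
            "val_loss": val_loss,
            "val_accuracy": float((logits_val.argmax(1) == y_val).mean()),
            "lr": opt.lr,
        })
        epochs_run = epoch + 1
        if verbose:
            print(f"epoch {epoch + 1}: {log[-1]}")

        if val_loss < best_val - cfg.early_stop_min_delta:
            best_val = val_loss
            best_weights = net.get_weights()
            wait_stop = wait_lr = 0
        else:
            wait_stop += 1
            wait_lr += 1
            if wait_lr >= cfg.lr_patience:
                opt.lr *= cfg.lr_factor
                wait_lr = 0
            if wait_stop >= cfg.early_stop_patience:
                break

    net.set_weights(best_weights)
    return TrainedModel(
        kind="deep", estimator=net, label_order=np.arange(model_cfg.classes),
        n_bands=model_cfg.input_len,
        config={"model": asdict(model_cfg), "train": asdict(cfg)},
        training_log=log, epochs_run=epochs_run,
    )


def train_classical(kind: str, dataset, gamma: float | None = None,
                    C: float | None = None, seed: int = 42) -> TrainedModel:
    """Fit LDA, QDA (library defaults) or the Gaussian SVM.

    For ``gsvm``, ``gamma`` and ``C`` may be supplied directly (e.g. values
    obtained from a previous genetic-algorithm run) or tuned by
    :func:`ga_optimize` beforehand.
    """
    X, y = np.asarray(dataset.X, float), np.asarray(dataset.y, int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if kind == "lda":
        est = LinearDiscriminantAnalysis()
    elif kind == "qda":
        n_features = X.shape[1]
        for c in classes:
            if (y == c).sum() < n_features + 1:
                raise ValueError(
                    f"class {c} has fewer than {n_features + 1} samples; "
                    "its covariance is singular"
                )
        est = QuadraticDiscriminantAnalysis()
    elif kind == "gsvm":
        if gamma is None or C is None:
            gamma, C, _ = ga_optimize(dataset, seed=seed)
        est = SVC(kernel="rbf", gamma=gamma, C=C, probability=True, random_state=seed)
    else:
        raise ValueError(f"unknown classical model kind {kind!r}")
    est.fit(X, y)
    return TrainedModel(kind=kind, estimator=est, label_order=est.classes_,
                        n_bands=X.shape[1],
                        config={"gamma": gamma, "C": C} if kind == "gsvm" else {})


def _cv_accuracy(dataset, gamma: float, C: float, folds: int, seed: int) -> float:
    X, y = dataset.X, dataset.y
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        if len(np.unique(y[tr])) < len(np.unique(y)):
            raise ValueError("a class is absent from a training fold")
        est = SVC(kernel="rbf", gamma=gamma, C=C)
        est.fit(X[tr], y[tr])
        accs.append(est.score(X[te], y[te]))
    return float(np.mean(accs))


def ga_optimize(
    dataset,
    folds: int = 5,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((1e-3, 1e2), (1e-2, 1e3)),
    seed: int = 42,
    population: int = 20,
    generations: int = 30,
    objective=None,
) -> tuple[float, float, float]:
    """Genetic-algorithm search for (gamma, C) maximizing k-fold CV accuracy.

    Works in log10 space with tournament selection (size 3), blend crossover
    and Gaussian mutation; fully seeded.  ``objective(gamma, C) -> score``
    may replace the CV objective (used by tests with analytic objectives).
    Returns ``(gamma, C, best_score)``.
    """
    (g_lo, g_hi), (c_lo, c_hi) = bounds
    if min(g_lo, g_hi, c_lo, c_hi) <= 0:
        raise ValueError("bounds must be positive")
    if objective is None:
        objective = lambda gamma, C: _cv_accuracy(dataset, gamma, C, folds, seed)
    rng = np.random.default_rng(seed)
    lo = np.log10([g_lo, c_lo])
    hi = np.log10([g_hi, c_hi])

    pop = rng.uniform(lo, hi, size=(population, 2))
    fitness = np.array([objective(*10.0**ind) for ind in pop])

    for _ in range(generations):
        children = []
        for _ in range(population):
            picks = rng.integers(0, population, size=3)
            p1 = pop[picks[np.argmax(fitness[picks])]]
            picks = rng.integers(0, population, size=3)
            p2 = pop[picks[np.argmax(fitness[picks])]]
            alpha = rng.uniform(0, 1, size=2)
            child = alpha * p1 + (1 - alpha) * p2
            child += rng.normal(0, 0.15, size=2)  # log-space mutation
            children.append(np.clip(child, lo, hi))
        child_fit = np.array([objective(*10.0**ind) for ind in children])
        merged = np.vstack([pop, children])
        merged_fit = np.concatenate([fitness, child_fit])
        keep = np.argsort(-merged_fit, kind="stable")[:population]
        pop, fitness = merged[keep], merged_fit[keep]

    best = pop[int(np.argmax(fitness))]
    return float(10.0 ** best[0]), float(10.0 ** best[1]), float(fitness.max())


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Class-probability matrix; rows sum to 1."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_bands:
        raise ValueError(f"expected {model.n_bands} bands, got {X.shape[1]}")
    if model.kind == "deep":
        probs = []
        for start in range(0, len(X), 4096):
            logits = model.estimator.forward(X[start : start + 4096, :, None], training=False)
            probs.append(nn.softmax(logits))
        return np.vstack(probs)
    return model.estimator.predict_proba(X)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Hard labels: argmax of the class probabilities."""
    return np.asarray(model.label_order)[predict_proba(model, X).argmax(axis=1)]
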