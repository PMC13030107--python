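"""Shared fixtures: session-scoped trained models amortize deep training."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fluorocold import models, synthetic_data

settings.register_profile(
    "fluorocold",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fluorocold")


def separable_spectrum_model(seed: int = 7) -> synthetic_data.SpectrumModel:
    """Well-separated three-class conditions: amplitudes 3/2/1, low noise."""
    return synthetic_data.SpectrumModel(
        class_amplitudes=(3.0, 2.0, 1.0), noise_sd=0.05, sample_cv=0.05, seed=seed
    )


@pytest.fixture(scope="session")
def separable_dataset():
    """300 spectra per class from the well-separated generator, seed 7."""
    return synthetic_data.sample_spectra(separable_spectrum_model(7), n_per_class=300)


@pytest.fixture(scope="session")
def deep_model_separable(separable_dataset):
    """Deep model trained on the separable benchmark.

    Uses the standard optimizer settings with a 60-epoch desk-scale budget;
    validation accuracy on this easy problem saturates within the first
    handful of epochs.
    """
    cfg = models.TrainConfig(max_epochs=60, early_stop_patience=50)
    return models.train_deep(separable_dataset, cfg=cfg)


def qc_benchmark_dataset(seed: int = 2026, displacement: float = 8.0):
    """2385 spectra with 82/21/22 planted atypical spectra per class.

    Clean spectra carry a rank-2 structure (independently jittered weights of
    the two chlorophyll emission peaks, as leaf physiology varies the
    F685/F740 balance); corrupted spectra are displaced by a fixed distance
    along random directions orthogonal to the clean two-component plane,
    emulating acquisition errors that leave the normal spectral subspace.
    Returns ``(dataset, planted_mask)``.
    """
    rng = np.random.default_rng(seed)
    wl = synthetic_data.default_wavelengths()
    g1 = np.exp(-0.5 * ((wl - 685) / 18) ** 2)
    g2 = np.exp(-0.5 * ((wl - 740) / 35) ** 2)
    sizes = {0: 826, 1: 780, 2: 779}          # totals sum to 2385
    planted = {0: 82, 1: 21, 2: 22}
    amps = {0: 3.0, 1: 2.2, 2: 1.5}

    def draw(c, k):
        w1 = amps[c] * rng.lognormal(-0.02, 0.2, (k, 1))
        w2 = 0.8 * amps[c] * rng.lognormal(-0.02, 0.2, (k, 1))
        return np.clip(w1 * g1 + w2 * g2 + rng.normal(0, 0.15, (k, 25)), 0, None)

    clean_blocks = {c: draw(c, n - planted[c]) for c, n in sizes.items()}
    bad_blocks = {c: draw(c, planted[c]) for c in sizes}
    from fluorocold import outlier_qc

    pca = outlier_qc.fit_pca(np.vstack(list(clean_blocks.values())), k=2)
    plane = pca.loadings @ pca.loadings.T
    blocks, labels, mask = [], [], []
    for c in sizes:
        u = rng.normal(size=(planted[c], 25))
        u -= u @ plane
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        blocks += [clean_blocks[c], bad_blocks[c] + displacement * u]
        labels += [np.full(len(clean_blocks[c]), c), np.full(planted[c], c)]
        mask += [np.zeros(len(clean_blocks[c]), bool), np.ones(planted[c], bool)]
    ds = synthetic_data.SpectralDataset(np.vstack(blocks), np.concatenate(labels))
    return ds, np.concatenate(mask)


@pytest.fixture(scope="session")
def band12_deep_model():
    """Deep model trained where class identity depends only on band 12."""
    ds = synthetic_data.single_band_dataset(300, informative_band=12, seed=11)
    cfg = models.TrainConfig(max_epochs=25, early_stop_patience=12, lr_patience=6)
    return models.train_deep(ds, cfg=cfg), ds
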