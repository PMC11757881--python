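import numpy as np
import pytest

from pdcconnect.mvar import MVARProcess


@pytest.fixture(scope="session")
def bivariate_process() -> MVARProcess:
    """Order-1 bivariate model with one-way coupling 1 -> 2 (hand-checkable)."""
    return MVARProcess([[[0.5, 0.0], [0.4, 0.5]]])


def random_stable_process(rng: np.random.Generator, n_channels: int = 4,
                          order: int = 2, density: float = 0.3,
                          radius: float = 0.9) -> MVARProcess:
    """Random sparse MVAR process rescaled to a target spectral radius."""
    coeffs = rng.normal(0, 0.4, (order, n_channels, n_channels))
    coeffs *= rng.random((order, n_channels, n_channels)) < density
    for ch in range(n_channels):
        coeffs[0, ch, ch] = rng.uniform(0.2, 0.5)
    proc = MVARProcess(coeffs)
    sr = proc.spectral_radius
    if sr > radius:
        # scaling lag-z coefficients by a**z scales every root by a
        a = radius / sr
        coeffs = coeffs * (a ** np.arange(1, order + 1))[:, None, None]
        proc = MVARProcess(coeffs)
    return proc


@pytest.fixture(scope="session")
def small_gamma_features():
    """Features of a small gamma-effect cohort, shared across classifier tests."""
    import pdcconnect as pc

    cfg = pc.gamma_effect_config(n_subjects_per_class=8, duration_s=30, seed=42)
    cohort = pc.make_cohort(cfg)
    segs = [s for rec in cohort.recordings for s in pc.segment(rec)]
    return pc.extract_features(segs, order=5)
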