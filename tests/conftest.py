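import numpy as np
import pytest

from thoraxgm import (ThoraxParams, analysis_template, default_template,
                      generate_sample)


@pytest.fixture(scope="session")
def full_template():
    return default_template()


@pytest.fixture(scope="session")
def reduced_template():
    return analysis_template()


@pytest.fixture(scope="session")
def small_sample(full_template):
    """Ten specimens per climate group with mild noise."""
    params = ThoraxParams(seed=11, n_per_group=10)
    return generate_sample(params, full_template)


@pytest.fixture(scope="session")
def clean_sample(full_template):
    """Noise-free, perfectly symmetric sample (one specimen per group)."""
    params = ThoraxParams(seed=12, n_per_group=1, size_cv=0.0,
                          ratio_sd=0.0, declination_sd_deg=0.0,
                          noise_sd_mm=0.0, asymmetry_sd_mm=0.0)
    return generate_sample(params, full_template)


def rigid_motion(coords, rng):
    """Apply a random proper rotation and translation to (k, 3) coords."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=50.0, size=3)
    return coords @ Q.T + t
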