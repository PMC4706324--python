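import numpy as np
import pytest

import csmra


@pytest.fixture(scope="session")
def small_phantom():
    """Noisy 32x32x16 phantom with masks (session-cached)."""
    return csmra.generate_phantom(shape=(32, 32, 16), noise_sd=0.02, seed=3)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return csmra.generate_phantom(shape=(32, 32, 16), noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def small_coils():
    return csmra.simulate_coils((32, 32, 16), n_coils=4, seed=5)


def random_sampling_mask(shape, rate, seed=0):
    """Directly constructed random mask for solver tests (no calibration;
    tiny grids cannot meet the calibration tolerance)."""
    rng = np.random.default_rng(seed)
    m = rng.random(shape) < rate
    m[shape[0] // 2, shape[1] // 2] = True  # DC
    return csmra.SamplingMask(m, rate, float(m.mean()), {"r0": 0.0}, seed)
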