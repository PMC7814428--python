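import numpy as np
import pytest

from owhto import ColumnModel, NoiseModel, simulate_experiment

#: published virtual-simulation grid, column order 20/10/0/-10, rows 0..30 by 5
REFERENCE_GRID = {
    20.0: [10.0, 10.0, 10.1, 10.3, 10.6, 10.9, 11.3],
    10.0: [10.0, 10.0, 10.0, 10.0, 10.0, 10.0, 10.0],
    0.0: [10.0, 10.0, 9.9, 9.7, 9.4, 9.1, 8.7],
    -10.0: [10.0, 9.9, 9.7, 9.4, 8.9, 8.3, 7.5],
}
CORRECTIONS = tuple(float(t) for t in range(0, 35, 5))


@pytest.fixture(scope="session")
def column() -> ColumnModel:
    return ColumnModel()


@pytest.fixture(scope="session")
def zero_noise_trials():
    return simulate_experiment(
        n_reps=3, noise=NoiseModel(sigma_point=0.0, sigma_mount=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def default_trials():
    return simulate_experiment(n_reps=10, noise=NoiseModel(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210118)
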