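import numpy as np
import pytest

from caldynet import SimConfig, simulate


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Small, fast simulated culture used by several suites."""
    return SimConfig(
        n_cells=10,
        field_width_um=300.0,
        field_height_um=300.0,
        conn_decay_um=80.0,
        conn_base_prob=0.8,
        active_fraction=1.0,
        event_rate_per_min=0.5,
        duration_s=300.0,
        event_duration_mean_s=8.0,
        event_duration_sd_s=2.0,
        amplitude_dff=0.5,
        noise_sd_dff=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    """(cell_map, ground_truth, traces) for the small culture."""
    return simulate(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
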