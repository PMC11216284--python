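"""Shared fixtures: small simulated chains and configurations."""

import numpy as np
import pytest

from chaintrack import build_layout, default_config
from chaintrack.simulator import SimConfig, synthesize_imu, three_link_truth


@pytest.fixture(scope="session")
def short_truth():
    """Three-link ground truth, 3 s at 100 Hz."""
    return three_link_truth(SimConfig(n_samples=300))


@pytest.fixture(scope="session")
def short_layout(short_truth):
    return build_layout(short_truth.topology)


@pytest.fixture(scope="session")
def noise_free_frames(short_truth):
    return synthesize_imu(short_truth, 0.0, 0.0, 0.0, rng=0)


@pytest.fixture(scope="session")
def noisy_frames(short_truth):
    cfg = SimConfig()
    return synthesize_imu(
        short_truth,
        cfg.accel_noise_std,
        cfg.gyro_noise_std,
        cfg.mag_noise_std,
        rng=np.random.default_rng(20240917),
    )


@pytest.fixture()
def config():
    return default_config()


@pytest.fixture()
def truth_state(short_truth, short_layout):
    """Callable: step index -> layout-ordered true mean vector."""

    def get(k):
        return short_truth.state_mean(k, short_layout)

    return get
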