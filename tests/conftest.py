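import dataclasses

import numpy as np
import pytest

from cortdev import SimConfig, build_toy_mesh, default_affected_cluster


@pytest.fixture(scope="session")
def mesh250():
    """500-vertex analysis mesh (250 per hemisphere), shared across tests."""
    return build_toy_mesh(250, 12345)


@pytest.fixture(scope="session")
def affected_cluster(mesh250):
    return default_affected_cluster(mesh250)


@pytest.fixture(scope="session")
def study_config():
    """Study-sized configuration: 45 subjects per cell, trajectory ages."""
    return SimConfig(n_per_cell=45, age_range=(6, 14), seed=42)


@pytest.fixture(scope="session")
def null_trajectory(study_config):
    """Trajectory model with no group effect (global null)."""
    return dataclasses.replace(
        study_config.trajectory, peak_shift_y=0.0, intercept_offset_mm=0.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
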