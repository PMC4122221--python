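"""Shared fixtures: small phantoms and solved systems reused across tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from durasim import (
    ConductivityVolume,
    ExperimentConfig,
    SourceConfig,
    Tissue,
    build_shell_phantom,
)

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


#: small nested-shell geometry (mm) used by fast unit tests
SMALL_RADII = [
    (Tissue.WHITE, 12.0),
    (Tissue.GRAY, 16.0),
    (Tissue.CSF, 18.0),
    (Tissue.DURA, 20.0),
    (Tissue.SKULL_HARD, 24.0),
    (Tissue.SCALP, 28.0),
]


@pytest.fixture(scope="session")
def small_phantom():
    """Uncorrugated 6-shell phantom, 2 mm voxels, 34^3 grid."""
    return build_shell_phantom(SMALL_RADII, (34, 34, 34), 2.0)


@pytest.fixture(scope="session")
def small_config():
    """Coarse (4 mm) full-head experiment configuration for smoke tests."""
    return ExperimentConfig(
        voxel_size=4.0,
        grid_shape=(36, 36, 36),
        source=SourceConfig(seed=7),
        n_trials=2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def uniform_cube_sigma(n: int = 8, sigma: float = 1.0, voxel_size: float = 1.0):
    return ConductivityVolume(np.full((n, n, n), sigma), voxel_size=voxel_size)
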