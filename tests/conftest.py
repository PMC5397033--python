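"""Shared fixtures: phantoms, small cohorts and a fitted appearance model."""

from __future__ import annotations

import numpy as np
import pytest

from bodysam.config import CalibrationTable
from bodysam.synthetic_phantoms import PhantomSpec, make_phantom

# pose jitter disabled: the three generative factors are the only variation
NO_POSE = {k: 0.0 for k in ("arm_angle", "forearm_angle",
                            "leg_angle", "shank_angle")}


@pytest.fixture(scope="session")
def calib() -> CalibrationTable:
    return CalibrationTable()


@pytest.fixture(scope="session")
def phantom():
    """Default noise-free phantom on the native scanner grid."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_pipeline():
    """One end-to-end pipeline run on a small cohort, reused across tests."""
    from bodysam.pipeline import run_pipeline

    return run_pipeline({
        "seed": 13,
        "cohort": {"n": 14, "noise_sd": 0.002,
                   "group_effects": {"sexlike": {"width": 2.5, "fat": -2.0}}},
        "channels": ["thickness", "leanness"],
        "scheme": "torso52",
    })


@pytest.fixture(scope="session")
def appearance(small_pipeline):
    return small_pipeline["model"].appearance


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
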