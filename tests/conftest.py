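import numpy as np
import pytest

from kinarom import (
    Anthropometry,
    ArmPoseSpec,
    NoiseModel,
    pose_to_skeleton,
    simulate_measurement_session,
)
from kinarom.arom import series_from_values


@pytest.fixture(scope="session")
def anthropometry():
    return Anthropometry()


@pytest.fixture
def clean_stream():
    """30-frame zero-noise hold at 90 deg abduction, straight elbow, right arm."""
    return simulate_measurement_session(
        [ArmPoseSpec("right", 90.0, 180.0)], noise=NoiseModel(0, 0, 0), seed=0)


@pytest.fixture
def tracked_frame():
    return pose_to_skeleton(ArmPoseSpec("right", 45.0, 150.0))


def constant_series(value=90.0, n=30, movement="shoulder_abduction", side="right"):
    return series_from_values([value] * n, movement, side)


def random_pose(rng: np.random.Generator) -> ArmPoseSpec:
    return ArmPoseSpec(
        side=str(rng.choice(["left", "right"])),
        shoulder_abduction=float(rng.uniform(0.0, 180.0)),
        elbow_flexion_included=float(rng.uniform(0.0, 180.0)),
    )
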