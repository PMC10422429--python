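import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from beetraffic import (AlignmentParams, FlightPattern, MotionParams,
                        OracleDetector, OracleDetectorConfig, SimConfig,
                        scaled_min_area, simulate)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

FLYING_MIX = {FlightPattern.STRAIGHT: 0.5,
              FlightPattern.INWARD_ZIGZAG: 0.2,
              FlightPattern.OUTWARD_ZIGZAG: 0.2,
              FlightPattern.PARALLEL: 0.1}


@pytest.fixture(scope="session")
def flying_scene():
    """30-frame scene whose bees are airborne in every frame."""
    cfg = SimConfig(n_bees=3, n_frames=30, pattern_mix=FLYING_MIX, seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def busy_flying_scene():
    """Denser all-flying scene for degradation statistics."""
    cfg = SimConfig(n_bees=8, n_frames=30, pattern_mix=FLYING_MIX, seed=11)
    return simulate(cfg)


@pytest.fixture
def test_motion_params():
    """Motion parameters with the area filter rescaled to 240x320 frames."""
    return MotionParams(min_contour_area=scaled_min_area((240, 320)))


@pytest.fixture
def perfect_detector():
    return OracleDetector(OracleDetectorConfig(seed=1))
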