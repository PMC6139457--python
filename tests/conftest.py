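import numpy as np
import pytest

from gazecal import (
    NoiseModel,
    RigGeometry,
    TrackerForwardModel,
    calibrate_session,
    generate_calibration_grid,
    generate_fixation_session,
)


@pytest.fixture(scope="session")
def rig() -> RigGeometry:
    """Primate-style rig: 20 x 9 cm work area, eye 30 cm above/behind center."""
    return RigGeometry.monkey_default()


@pytest.fixture(scope="session")
def tracker(rig) -> TrackerForwardModel:
    return TrackerForwardModel.for_rig(rig)


@pytest.fixture(scope="session")
def grid(rig) -> np.ndarray:
    return generate_calibration_grid(rig.work_area_cm)


@pytest.fixture(scope="session")
def clean_session(grid, tracker, rig):
    """Noise-free artificial-eye calibration session on the 5x5 grid."""
    return generate_fixation_session(grid, tracker, NoiseModel(), rig, seed=1)


@pytest.fixture(scope="session")
def quartic_model(clean_session):
    """Order-4 regrid-then-fit calibration from the clean session."""
    return calibrate_session(clean_session, order=4, fit_on="mesh")
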