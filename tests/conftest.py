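import numpy as np
import pytest

from freekick.behavior import BehaviorParams, CorruptionParams, generate_session
from freekick.preprocess import run_qc
from freekick.scene import Viewpoint, WallSpec, visibility_onset
from freekick.trajectory import AeroParams, experiment_design, solve_kick


@pytest.fixture(scope="session")
def aero():
    return AeroParams()


@pytest.fixture(scope="session")
def design():
    return experiment_design()


@pytest.fixture(scope="session")
def experimental(design):
    return [k for k in design if k.kind == "experimental"]


@pytest.fixture(scope="session")
def solved(experimental, aero):
    """The 18 experimental trajectories solved once per test session."""
    return {k.label: solve_kick(k, aero) for k in experimental}


@pytest.fixture(scope="session")
def solved_full(design, aero):
    """All 63 trajectories (experimental + dummy)."""
    return {k.label: solve_kick(k, aero) for k in design}


@pytest.fixture(scope="session")
def wall():
    return WallSpec()


@pytest.fixture(scope="session")
def viewpoint():
    return Viewpoint()


@pytest.fixture(scope="session")
def visibility(solved, wall, viewpoint):
    return {
        label: visibility_onset(traj, wall, viewpoint)
        for label, traj in solved.items()
    }


@pytest.fixture(scope="session")
def clean_session(solved, visibility):
    """Two artefact-free participants, experimental trials only."""
    behavior = BehaviorParams()
    corruption = CorruptionParams(0.0, 0.0, 0.05, 0.0)
    return generate_session(
        solved, visibility, behavior, corruption, 2, 424242,
        experimental_reps=5, dummy_reps=0,
    )


@pytest.fixture(scope="session")
def clean_qc(clean_session):
    return run_qc(clean_session)
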