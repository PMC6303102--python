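import numpy as np
import pytest

from ttftimer import (
    DEFAULT_CONSTANTS,
    Trajectory,
    build_default_topology,
    load_fixture,
    load_identity_map,
    load_phenotype_table,
    load_stage_table,
)


@pytest.fixture(scope="session")
def topology():
    return build_default_topology()


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def identity_map():
    return load_identity_map()


@pytest.fixture(scope="session")
def phenotype_table():
    return load_phenotype_table()


@pytest.fixture(scope="session")
def stage_table():
    return load_stage_table()


@pytest.fixture(scope="session")
def reference_params():
    """A consistent circuit found by the packaged fixture search."""
    return load_fixture("consistent")


@pytest.fixture(scope="session")
def robust_params():
    """A consistent circuit with robustness score > 80."""
    return load_fixture("robust")


@pytest.fixture(scope="session")
def decay_params():
    """A robust, decay-dominant circuit with stage-callable WT inductions."""
    return load_fixture("decay_dominant")


def square_trajectory(windows, horizon=400.0, high=10.0):
    """Toy trajectory: each TTF at ``high`` inside its (start, end) window.

    ``windows`` maps TTF name -> (start, end); absent TTFs stay at zero.
    """
    times = np.arange(0.0, horizon + 1.0)
    ttfs = ("Hb", "Kr", "Pdm", "Cas")
    levels = np.zeros((len(times), len(ttfs)))
    for j, ttf in enumerate(ttfs):
        if ttf in windows:
            lo, hi = windows[ttf]
            levels[(times >= lo) & (times < hi), j] = high
    return Trajectory(times, levels, ttfs)


@pytest.fixture
def toy_trajectory():
    """Hb high on [0, 40), then Kr high on [40, 80)."""
    return square_trajectory({"Hb": (0, 40), "Kr": (40, 80)}, horizon=100.0)
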