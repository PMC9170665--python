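import numpy as np
import pytest

from osari import data_io, simulator, task_model


@pytest.fixture
def params():
    return task_model.TaskParameters()


@pytest.fixture
def participant():
    return simulator.ParticipantParams()


@pytest.fixture
def default_outcomes(params, participant):
    """One full default session from the race-model simulator (seed-fixed)."""
    return simulator.simulate_session(participant, params, seed=7)


@pytest.fixture
def default_frame(default_outcomes):
    return data_io.outcomes_to_frame(default_outcomes, "s01")


def stop_only_session(n_stop: int) -> list[task_model.BlockSpec]:
    """A single mixed test block of stop trials, for staircase studies."""
    return [task_model.BlockSpec("testMixed", 0, n_stop)]


def lift_at(t_go: float):
    """Responder that always lifts at t_go on go trials and never on stops."""

    def respond(trial, ssd_s, rng):
        return t_go if trial.signal == task_model.GO else None

    return respond


def always_lift_at(t: float):
    """Responder that lifts at t regardless of the signal."""

    def respond(trial, ssd_s, rng):
        return t

    return respond
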