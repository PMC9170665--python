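"""Forward simulation of task performance under the independent horse-race model.

Each trial is a race between a *go* process (the planned key lift, timed at
the target) and, on stop trials, a *stop* process launched when the bar halts
at the SSD.  The response is emitted iff the go process finishes no later
than the stop process; otherwise the prepared lift is cancelled.  Finishing
times are truncated-normal: the go distribution is centred near the target
time, the stop distribution's mean is the participant's true SSRT.  Context
independence holds by construction — the go finishing-time distribution is
identical on go and stop trials — which is exactly the assumption the
nonparametric SSRT estimator relies on.

Optional imperfections: *trigger failures* (the stop process is never
launched, so the race collapses to the go process) and spontaneous lifts
during the variable start interval (which restart the trial).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from . import data_io
from .task_model import (
    STOP,
    BlockSpec,
    TaskParameters,
    TrialOutcome,
    TrialSpec,
    START_INTERVAL_LIFT,
    make_default_session,
    run_session,
)

__all__ = [
    "ParticipantParams",
    "SimulatedCohortSpec",
    "draw_go_finish",
    "draw_stop_finish",
    "simulate_stop_trial",
    "race_responder",
    "simulate_session",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ParticipantParams:
    """Generative parameters of one simulated participant.

    ``go_mean``/``go_sd`` describe the lift time from fill onset (seconds,
    near the 0.8 s target for a well-trained participant); ``ssrt_mean``/
    ``ssrt_sd`` the latency of the stop process.  ``p_trigger_failure`` is
    the per-stop-trial probability that the stop process never launches;
    ``p_start_interval_lift`` the per-attempt probability of lifting before
    the bar starts to fill.
    """

    go_mean: float = 0.8
    go_sd: float = 0.05
    ssrt_mean: float = 0.2
    ssrt_sd: float = 0.03
    p_trigger_failure: float = 0.0
    p_start_interval_lift: float = 0.0

    def __post_init__(self) -> None:
        if self.go_mean <= 0:
            raise ValueError("go_mean must be positive")
        if self.go_sd < 0 or self.ssrt_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.ssrt_mean < 0:
            raise ValueError("ssrt_mean must be nonnegative")
        for p in (self.p_trigger_failure, self.p_start_interval_lift):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedCohortSpec:
    """A cohort of participants to simulate, one seed stream per member."""

    n_participants: int
    participants: tuple[ParticipantParams, ...]
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        if len(self.participants) != self.n_participants:
            raise ValueError("need one ParticipantParams per participant")


def _truncnorm_draw(mean: float, sd: float, rng: np.random.Generator) -> float:
    """One draw from Normal(mean, sd) truncated to (0, inf)."""
    if sd == 0:
        return mean
    a = (0.0 - mean) / sd  # lower bound in standard units; upper is +inf
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def draw_go_finish(participant: ParticipantParams, rng: np.random.Generator) -> float:
    """Sample one go-process finishing time (s from fill onset).

    Values beyond the trial duration mean the key was never lifted before the
    bar filled (a go omission).
    """
    return _truncnorm_draw(participant.go_mean, participant.go_sd, rng)


def draw_stop_finish(participant: ParticipantParams, rng: np.random.Generator) -> float:
    """Sample one stop-process latency (s from the bar halting)."""
    return _truncnorm_draw(participant.ssrt_mean, participant.ssrt_sd, rng)


def simulate_stop_trial(
    t_go: float,
    ssd: float,
    t_stop: float,
    triggered: bool,
    trial_duration: float = 1.0,
) -> tuple[bool, Optional[float]]:
    """Resolve the race on a single stop trial.

    Returns ``(responded, rt)``.  With the stop process triggered, the
    response escapes iff the go process finishes no later than the stop
    process finishes (``t_go <= ssd + t_stop``; the go process wins ties).
    An untriggered stop process leaves only the go process running.  Either
    way a go finish beyond the trial duration is no response.
    """
    if ssd < 0 or t_stop < 0:
        raise ValueError("ssd and t_stop must be nonnegative")
    wins = t_go <= ssd + t_stop if triggered else True
    if wins and t_go <= trial_duration:
        return True, t_go
    return False, None


def race_responder(participant: ParticipantParams, params: TaskParameters):
    """Build a responder callback for :func:`osari.task_model.run_session`.

    Per attempt the draw order is fixed: start-interval-lift Bernoulli, go
    finishing time, then (stop trials only) trigger Bernoulli and stop
    latency — so sessions replay bit-identically from a seed.
    """

    def respond(
        trial: TrialSpec, ssd_s: Optional[float], rng: np.random.Generator
    ) -> Optional[float]:
        if participant.p_start_interval_lift > 0 and (
            rng.random() < participant.p_start_interval_lift
        ):
            return START_INTERVAL_LIFT
        t_go = draw_go_finish(participant, rng)
        if trial.signal == STOP:
            triggered = True
            if participant.p_trigger_failure > 0:
                triggered = rng.random() >= participant.p_trigger_failure
            t_stop = draw_stop_finish(participant, rng)
            responded, rt = simulate_stop_trial(
                t_go, ssd_s, t_stop, triggered, params.trial_duration
            )
            return rt if responded else None
        return t_go if t_go <= params.trial_duration else None

    return respond


def simulate_session(
    participant: ParticipantParams,
    task_params: TaskParameters | None = None,
    seed: int | None = 0,
    session: list[BlockSpec] | None = None,
    *,
    participant_id: str | None = None,
    path: str | Path | None = None,
) -> list[TrialOutcome]:
    """Simulate a full session; optionally write it as a task data file.

    With no explicit ``session`` the default six-block composition is used.
    Identical ``seed`` (and parameters) gives identical outcome lists.
    """
    params = task_params if task_params is not None else TaskParameters()
    blocks = session if session is not None else make_default_session(params)
    outcomes = run_session(blocks, race_responder(participant, params), params, seed)
    if path is not None:
        data_io.write_trials(outcomes, participant_id or "sim", path)
    return outcomes


def simulate_cohort(
    spec: SimulatedCohortSpec,
    task_params: TaskParameters | None = None,
    out_dir: str | Path | None = None,
    session: list[BlockSpec] | None = None,
    *,
    timestamp=None,
) -> dict[str, list[TrialOutcome]]:
    """Simulate every participant of a cohort.

    Per-participant seeds are spawned deterministically from the master seed.
    When ``out_dir`` is given, one data file per participant plus a
    ``manifest.txt`` of true generative parameters (for recovery studies)
    are written there.
    """
    params = task_params if task_params is not None else TaskParameters()
    seeds = np.random.SeedSequence(spec.master_seed).generate_state(spec.n_participants)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    sessions: dict[str, list[TrialOutcome]] = {}
    manifest_rows = []
    for i, (pp, s) in enumerate(zip(spec.participants, seeds), start=1):
        pid = f"sim{i:03d}"
        out_path = None
        if out_dir is not None:
            out_path = Path(out_dir) / data_io.build_filename(pid, timestamp)
        sessions[pid] = simulate_session(
            pp, params, int(s % (2**31)), session, participant_id=pid, path=out_path
        )
        manifest_rows.append((pid, pp))
    if out_dir is not None:
        data_io.write_manifest(manifest_rows, Path(out_dir) / "manifest.txt")
    return sessions
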