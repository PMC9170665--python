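"""Deterministic logic of the anticipated-response-inhibition (ARI) task.

The task presents a vertical bar that fills over a fixed trial duration
(default 1 s).  On *go* trials the participant releases a held key so the bar
stops as close as possible to a target drawn at a fixed fraction of the bar
height (default 80%, i.e. 800 ms into the trial).  On *stop* trials the bar
halts on its own at the stop-signal delay (SSD) and the participant must keep
the key depressed until the trial would have ended.  The SSD is adapted with a
1-up/1-down staircase that tracks the delay at which the participant responds
on half of the stop trials.

This module contains only the arithmetic and bookkeeping of that task —
session composition, trial scheduling, staircase updates, feedback
classification and the stimulus-position formulas.  No graphics, no clocks,
no keyboard: a *responder* callback stands in for the participant, which makes
every run exactly reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "TaskParameters",
    "BlockSpec",
    "TrialSpec",
    "StaircaseState",
    "TrialOutcome",
    "GO",
    "STOP",
    "START_INTERVAL_LIFT",
    "make_default_session",
    "schedule_block",
    "update_ssd",
    "target_time",
    "classify_go_feedback",
    "classify_stop_outcome",
    "bar_position",
    "distance_per_frame",
    "run_session",
]

#: signal codes used throughout (and in the data files)
GO = 0
STOP = 1

#: sentinel a responder returns to indicate a key lift during the variable
#: start interval (before the bar begins to fill); the trial restarts.
START_INTERVAL_LIFT = -1.0

BLOCK_LABELS = ("practiceGo", "testGo", "practiceMixed", "testMixed")


@dataclass(frozen=True)
class TaskParameters:
    """All tunable task constants.

    Times for the SSD machinery are integer-friendly milliseconds; trial-level
    times (durations, RTs) are seconds, matching the output file convention.
    """

    trial_duration: float = 1.0          # s, time for the bar to fill fully
    bar_height: float = 15.0             # cm
    bar_width: float = 3.0               # cm
    target_fraction: float = 0.8         # target at this fraction of bar height
    feedback_bands: tuple[float, float, float] = (20.0, 40.0, 60.0)  # ms
    initial_ssd: float = 500.0           # ms
    step_size: float = 25.0              # ms, staircase step
    min_ssd: float = 50.0                # ms
    max_ssd: float = 775.0               # ms
    early_lift_window: float = 100.0     # ms, lifts sooner get encouragement
    start_interval_range: tuple[float, float] = (0.5, 1.0)  # s, uniform
    ssd_mode: str = "staircase"          # {"staircase", "fixed"}
    trial_order: str = "random"          # {"random", "sequential"}

    def __post_init__(self) -> None:
        if not 0 < self.target_fraction < 1:
            raise ValueError("target_fraction must lie in (0, 1)")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.bar_height <= 0 or self.bar_width <= 0:
            raise ValueError("bar dimensions must be positive")
        b = self.feedback_bands
        if len(b) != 3 or not (0 < b[0] < b[1] < b[2]):
            raise ValueError("feedback_bands must be three ascending positive thresholds")
        if not (self.min_ssd <= self.initial_ssd <= self.max_ssd):
            raise ValueError("require min_ssd <= initial_ssd <= max_ssd")
        if not (0 < self.min_ssd and self.max_ssd < self.trial_duration * 1000.0):
            raise ValueError("SSD bounds must lie within (0, trial_duration) in ms")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.early_lift_window < 0:
            raise ValueError("early_lift_window must be nonnegative")
        lo, hi = self.start_interval_range
        if not (0 <= lo <= hi):
            raise ValueError("start_interval_range must be an ordered nonnegative pair")
        if self.ssd_mode not in ("staircase", "fixed"):
            raise ValueError("ssd_mode must be 'staircase' or 'fixed'")
        if self.trial_order not in ("random", "sequential"):
            raise ValueError("trial_order must be 'random' or 'sequential'")


@dataclass(frozen=True)
class BlockSpec:
    """Composition of one block of trials.

    ``signal_order`` preserves the row order of a condition table (used by
    sequential scheduling); when absent, go rows precede stop rows.
    ``fixed_stop_times`` pins each stop row's SSD for ssd_mode='fixed'.
    """

    label: str
    n_go: int
    n_stop: int
    fixed_stop_times: Optional[tuple[float, ...]] = None
    signal_order: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.label not in BLOCK_LABELS:
            raise ValueError(f"unknown block label {self.label!r}")
        if self.n_go < 0 or self.n_stop < 0:
            raise ValueError("trial counts must be nonnegative")
        if self.signal_order is not None:
            order = tuple(self.signal_order)
            if sorted(order) != sorted([GO] * self.n_go + [STOP] * self.n_stop):
                raise ValueError("signal_order must contain exactly n_go gos and n_stop stops")
        if self.fixed_stop_times is not None and len(self.fixed_stop_times) != self.n_stop:
            raise ValueError("fixed_stop_times must have one entry per stop trial")

    @property
    def n_trials(self) -> int:
        return self.n_go + self.n_stop


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial before it is run."""

    block_label: str
    block_index: int      # 1-based, counted per block type
    trial_index: int      # 1-based within block
    signal: int           # GO or STOP
    planned_ssd: Optional[float] = None  # ms; fixed mode only


@dataclass(frozen=True)
class StaircaseState:
    """Current SSD of the 1-up/1-down tracker, in ms."""

    current_ssd: float


@dataclass(frozen=True)
class TrialOutcome:
    """Record of one completed trial.

    ``ssd`` is NaN on go trials; ``rt`` is NaN whenever no response was made
    (correct stops and go omissions).  ``early_lift_restarts`` counts aborted
    starts (lifts during the variable start interval) that preceded this
    trial; ``encouragement`` flags a lift within the first
    ``early_lift_window`` ms of the fill.
    """

    block_label: str
    block_index: int
    trial_index: int
    signal: int
    response: int                 # 1 = key lifted, 0 = no response
    ssd: float                    # ms; NaN for go trials
    rt: float                     # s from fill onset; NaN if response == 0
    feedback_band: str            # green / yellow / orange / red
    early_lift_restarts: int = 0
    encouragement: bool = False


# ---------------------------------------------------------------------------
# session construction and scheduling

def make_default_session(
    params: TaskParameters,
    *,
    include_practice: bool = True,
    include_test_go: bool = True,
) -> list[BlockSpec]:
    """Default session: practiceGo(10), testGo(30), practiceMixed(15+5),
    then three testMixed blocks of 60 go + 20 stop trials (300 trials total).

    The two toggles mirror the task's start-up checkboxes: disabling practice
    drops both practice blocks; disabling the test go block drops only it.
    """
    blocks: list[BlockSpec] = []
    if include_practice:
        blocks.append(BlockSpec("practiceGo", 10, 0))
    if include_test_go:
        blocks.append(BlockSpec("testGo", 30, 0))
    if include_practice:
        blocks.append(BlockSpec("practiceMixed", 15, 5))
    blocks.extend(BlockSpec("testMixed", 60, 20) for _ in range(3))
    return blocks


def schedule_block(
    spec: BlockSpec,
    order: str,
    rng: np.random.Generator | int | None = None,
    *,
    block_index: int = 1,
) -> list[TrialSpec]:
    """Lay out one block as a list of :class:`TrialSpec`.

    ``order='sequential'`` preserves the condition-table row order
    (``spec.signal_order``, or gos-then-stops if none was given);
    ``order='random'`` applies a seeded uniform permutation of the rows.
    A row's fixed stop time travels with it through the permutation.
    """
    if order not in ("random", "sequential"):
        raise ValueError("order must be 'random' or 'sequential'")
    base_signals = list(
        spec.signal_order
        if spec.signal_order is not None
        else [GO] * spec.n_go + [STOP] * spec.n_stop
    )
    # attach fixed stop times to stop rows in table order
    planned: list[Optional[float]] = []
    stop_iter = iter(spec.fixed_stop_times or ())
    for s in base_signals:
        planned.append(next(stop_iter, None) if s == STOP else None)

    idx = np.arange(len(base_signals))
    if order == "random":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        idx = gen.permutation(idx)
    return [
        TrialSpec(
            block_label=spec.label,
            block_index=block_index,
            trial_index=t + 1,
            signal=base_signals[i],
            planned_ssd=planned[i],
        )
        for t, i in enumerate(idx)
    ]


# ---------------------------------------------------------------------------
# staircase

def update_ssd(state: StaircaseState, stop_success: bool, params: TaskParameters) -> StaircaseState:
    """1-up/1-down SSD update after a stop trial.

    A successful stop makes the next stop trial harder (+step); a failed stop
    makes it easier (−step).  The result is clamped to [min_ssd, max_ssd].
    Go trials never touch the staircase.
    """
    delta = params.step_size if stop_success else -params.step_size
    new = min(max(state.current_ssd + delta, params.min_ssd), params.max_ssd)
    return StaircaseState(current_ssd=new)


# ---------------------------------------------------------------------------
# stimulus / feedback arithmetic

def target_time(params: TaskParameters) -> float:
    """Seconds from fill onset at which the bar reaches the target."""
    return params.trial_duration * params.target_fraction


def classify_go_feedback(rt: float, params: TaskParameters) -> str:
    """Feedback band for a go response: absolute error from the target time.

    Error <= 20 ms -> green, <= 40 -> yellow, <= 60 -> orange, else red
    (each band half-open above its lower threshold; 'within' includes the
    bound).  Symmetric above/below the target.
    """
    if not np.isfinite(rt):
        raise ValueError("rt must be a finite response time in seconds")
    err_ms = abs(rt - target_time(params)) * 1000.0
    g, y, o = params.feedback_bands
    if err_ms <= g:
        return "green"
    if err_ms <= y:
        return "yellow"
    if err_ms <= o:
        return "orange"
    return "red"


def classify_stop_outcome(lifted_before_trial_end: bool) -> str:
    """'success' if the key stayed down through the full trial, else 'failure'.

    Any lift after fill onset on a stop trial — even before the bar halts —
    counts as a failed stop.
    """
    return "failure" if lifted_before_trial_end else "success"


def bar_position(elapsed: float, params: TaskParameters) -> float:
    """Bar height in cm after ``elapsed`` seconds (time-approach rendering).

    Position = total distance * (time elapsed / trial duration), capped at
    the full bar height.
    """
    if elapsed < 0:
        raise ValueError("elapsed time cannot be negative")
    return min(params.bar_height * (elapsed / params.trial_duration), params.bar_height)


def distance_per_frame(refresh_rate: float, params: TaskParameters) -> float:
    """Bar travel per screen refresh in cm (space-approach rendering).

    Distance per frame = total distance * (time per frame / total travel time).
    """
    if refresh_rate <= 0:
        raise ValueError("refresh_rate must be positive")
    return params.bar_height * ((1.0 / refresh_rate) / params.trial_duration)


# ---------------------------------------------------------------------------
# session runner

#: Responder: called with (trial, ssd_seconds_or_None, rng) and returns the
#: key-lift time in seconds from fill onset, None for no lift, or
#: START_INTERVAL_LIFT (any negative value) for a lift before fill onset.
Responder = Callable[[TrialSpec, Optional[float], np.random.Generator], Optional[float]]

_MAX_RESTARTS = 10_000


def run_session(
    session: Sequence[BlockSpec],
    responder: Responder,
    params: TaskParameters,
    rng_seed: int | np.random.Generator | None = 0,
) -> list[TrialOutcome]:
    """Run every block of ``session`` against a responder callback.

    Staircase carry-over follows the task's rules: the SSD starts at
    ``initial_ssd`` for the practice mixed block, resets at the first test
    mixed block, and is then carried across subsequent test mixed blocks.
    Lifts during the variable start interval abort and restart the trial
    without consuming a trial index.  One seeded generator drives all
    stochastic draws (block order, start intervals, responder noise) in a
    fixed order, so a session is fully reproducible from its seed.
    """
    if len(session) == 0:
        raise ValueError("session must contain at least one block")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    outcomes: list[TrialOutcome] = []
    state = StaircaseState(params.initial_ssd)
    seen_test_mixed = False
    block_counts: dict[str, int] = {}

    for spec in session:
        block_counts[spec.label] = block_counts.get(spec.label, 0) + 1
        if spec.label == "practiceMixed":
            state = StaircaseState(params.initial_ssd)
        elif spec.label == "testMixed" and not seen_test_mixed:
            state = StaircaseState(params.initial_ssd)
            seen_test_mixed = True

        trials = schedule_block(
            spec, params.trial_order, rng, block_index=block_counts[spec.label]
        )
        for trial in trials:
            outcome, state = _run_trial(trial, responder, params, state, rng)
            outcomes.append(outcome)
    return outcomes


def _run_trial(
    trial: TrialSpec,
    responder: Responder,
    params: TaskParameters,
    state: StaircaseState,
    rng: np.random.Generator,
) -> tuple[TrialOutcome, StaircaseState]:
    if trial.signal == STOP:
        ssd_ms = trial.planned_ssd if params.ssd_mode == "fixed" else state.current_ssd
        if ssd_ms is None:
            raise ValueError(
                f"fixed ssd_mode but no planned SSD for {trial.block_label} "
                f"trial {trial.trial_index}"
            )
        ssd_s: Optional[float] = ssd_ms / 1000.0
    else:
        ssd_ms, ssd_s = math.nan, None

    restarts = 0
    while True:
        rng.uniform(*params.start_interval_range)  # variable start interval draw
        try:
            lift = responder(trial, ssd_s, rng)
        except Exception as exc:
            raise RuntimeError(
                f"responder failed on {trial.block_label} block "
                f"{trial.block_index} trial {trial.trial_index}"
            ) from exc
        if lift is not None and lift < 0:  # lifted during the start interval
            restarts += 1
            if restarts > _MAX_RESTARTS:
                raise RuntimeError("responder never completed the trial (endless restarts)")
            continue
        break

    encouragement = lift is not None and lift * 1000.0 <= params.early_lift_window

    if trial.signal == GO:
        if lift is None or lift > params.trial_duration:
            # omission: the bar filled to the top with the key still down
            response, rt, band = 0, math.nan, "red"
        else:
            response, rt = 1, float(lift)
            band = classify_go_feedback(rt, params)
        new_state = state  # go trials never modify the staircase
    else:
        lifted = lift is not None and lift <= params.trial_duration
        if classify_stop_outcome(lifted) == "success":
            response, rt, band = 0, math.nan, "green"
            success = True
        else:
            response, rt, band = 1, float(lift), "red"
            success = False
        new_state = (
            update_ssd(state, success, params) if params.ssd_mode == "staircase" else state
        )

    outcome = TrialOutcome(
        block_label=trial.block_label,
        block_index=trial.block_index,
        trial_index=trial.trial_index,
        signal=trial.signal,
        response=response,
        ssd=float(ssd_ms) if trial.signal == STOP else math.nan,
        rt=rt,
        feedback_band=band,
        early_lift_restarts=restarts,
        encouragement=bool(encouragement),
    )
    return outcome, new_state
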