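"""Readers and writers for the task's plain-text data formats.

The trial file is a space-delimited ``.txt`` table with the columns

    id block trialType trial signal response ssd rt

one row per trial: ``signal`` (0 = go, 1 = stop), ``response`` (1 = go
response made, 0 = no response), ``ssd`` the stop-signal delay in seconds
(literally ``NaN`` on go trials) and ``rt`` the response time in seconds
(literally ``NaN`` when no response was made — correct stops and go
omissions).  The STOP-IT dialect is the same table without the ``trialType``
column.  Both ssd and rt are written in seconds; note that task parameters
quote SSDs in milliseconds — conversion happens at this boundary.

File names follow ``ID_OSARI_yyyy_month_d_hhmm`` with the month spelled out
and the day unpadded, so repeat sessions of one participant never collide.
"""

from __future__ import annotations

import datetime as _dt
import math
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .task_model import GO, STOP, BlockSpec, TaskParameters, TrialOutcome, classify_go_feedback

__all__ = [
    "COLUMNS",
    "write_trials",
    "read_trials",
    "outcomes_to_frame",
    "frame_to_outcomes",
    "build_filename",
    "parse_filename",
    "read_condition_table",
    "write_condition_table",
    "write_manifest",
    "read_manifest",
]

COLUMNS = ["id", "block", "trialType", "trial", "signal", "response", "ssd", "rt"]
STOPIT_COLUMNS = [c for c in COLUMNS if c != "trialType"]

_NUM_FMT = "%.6g"


def _fmt(x: float) -> str:
    return "NaN" if (x is None or (isinstance(x, float) and math.isnan(x))) else _NUM_FMT % x


def outcomes_to_frame(outcomes: Sequence[TrialOutcome], participant_id: str) -> pd.DataFrame:
    """Tabulate trial outcomes in file column order (ssd converted to s)."""
    return pd.DataFrame(
        {
            "id": [participant_id] * len(outcomes),
            "block": [o.block_index for o in outcomes],
            "trialType": [o.block_label for o in outcomes],
            "trial": [o.trial_index for o in outcomes],
            "signal": [o.signal for o in outcomes],
            "response": [o.response for o in outcomes],
            "ssd": [o.ssd / 1000.0 for o in outcomes],
            "rt": [o.rt for o in outcomes],
        },
        columns=COLUMNS,
    )


def frame_to_outcomes(df: pd.DataFrame, params: TaskParameters | None = None) -> list[TrialOutcome]:
    """Rebuild :class:`TrialOutcome` records from a parsed trial table.

    The feedback band is not stored in the file; it is reclassified from the
    recorded RT (go trials) or the response flag (stop trials).
    """
    params = params if params is not None else TaskParameters()
    out = []
    for row in df.itertuples(index=False):
        signal, response, rt = int(row.signal), int(row.response), float(row.rt)
        if signal == GO:
            band = classify_go_feedback(rt, params) if response == 1 else "red"
        else:
            band = "green" if response == 0 else "red"
        out.append(
            TrialOutcome(
                block_label=str(row.trialType),
                block_index=int(row.block),
                trial_index=int(row.trial),
                signal=signal,
                response=response,
                ssd=float(row.ssd) * 1000.0 if signal == STOP else math.nan,
                rt=rt,
                feedback_band=band,
            )
        )
    return out


def write_trials(
    outcomes: Sequence[TrialOutcome] | pd.DataFrame,
    participant_id: str,
    path: str | Path,
) -> Path:
    """Write a trial table in the exact ``.txt`` schema (space-delimited).

    Undefined values are rendered literally as ``NaN``.  An empty session
    produces a header-only file.
    """
    df = (
        outcomes.copy()
        if isinstance(outcomes, pd.DataFrame)
        else outcomes_to_frame(outcomes, participant_id)
    )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(" ".join(COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.id} {row.block} {row.trialType} {row.trial} "
                f"{row.signal} {row.response} {_fmt(row.ssd)} {_fmt(row.rt)}\n"
            )
    return path


class TrialFileError(ValueError):
    """Malformed trial file (missing columns or invalid cell values)."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise TrialFileError(msg)


def read_trials(path: str | Path, dialect: str = "OSARI") -> pd.DataFrame:
    """Parse a trial ``.txt`` file, validating the schema row by row.

    ``dialect='OSARI'`` requires the ``trialType`` column; ``dialect='STOP-IT'``
    accepts its absence (a ``trialType`` of ``testMixed`` is filled in so the
    analysis code has a uniform frame).  Signal/response codes outside {0, 1},
    non-numeric ssd/rt, and NaN placement violating the schema are rejected
    with the offending row number (1-based, excluding the header).
    """
    if dialect not in ("OSARI", "STOP-IT"):
        raise ValueError("dialect must be 'OSARI' or 'STOP-IT'")
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    expected = COLUMNS if dialect == "OSARI" else STOPIT_COLUMNS
    missing = [c for c in expected if c not in df.columns]
    _require(not missing, f"{path.name}: missing column(s) {missing} for dialect {dialect}")
    if dialect == "STOP-IT" and "trialType" not in df.columns:
        df["trialType"] = "testMixed"
    df = df[COLUMNS]

    parsed = df.copy()
    for col in ("block", "trial", "signal", "response"):
        parsed[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("ssd", "rt"):
        parsed[col] = pd.to_numeric(df[col].replace("NaN", "nan"), errors="coerce")

    for i, row in enumerate(parsed.itertuples(index=False), start=1):
        for col in ("block", "trial", "signal", "response"):
            _require(not math.isnan(getattr(row, col)), f"row {i}: non-numeric {col!r}")
        _require(row.signal in (0, 1), f"row {i}: signal must be 0 or 1, got {row.signal:g}")
        _require(row.response in (0, 1), f"row {i}: response must be 0 or 1, got {row.response:g}")
        raw_ssd, raw_rt = df.iloc[i - 1]["ssd"], df.iloc[i - 1]["rt"]
        for col, raw, val in (("ssd", raw_ssd, row.ssd), ("rt", raw_rt, row.rt)):
            _require(
                raw == "NaN" or not math.isnan(val),
                f"row {i}: {col!r} must be numeric or the literal 'NaN', got {raw!r}",
            )
        _require(
            (row.signal == 0) == math.isnan(row.ssd),
            f"row {i}: ssd must be NaN exactly on go trials",
        )
        _require(
            (row.response == 0) == math.isnan(row.rt),
            f"row {i}: rt must be NaN exactly when no response was made",
        )

    for col in ("block", "trial", "signal", "response"):
        parsed[col] = parsed[col].astype(int)
    return parsed


# ---------------------------------------------------------------------------
# file naming

_MONTHS = [
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
]
_NAME_RE = re.compile(
    r"^(?P<id>.+)_OSARI_(?P<year>\d{4})_(?P<month>[A-Za-z]+)_(?P<day>\d{1,2})_(?P<hm>\d{4})$"
)


def build_filename(participant_id: str, timestamp: _dt.datetime | None = None) -> str:
    """``ID_OSARI_yyyy_month_d_hhmm`` (+ ``.txt``): month spelled out, day unpadded."""
    if not participant_id:
        raise ValueError("participant_id must be nonempty")
    ts = timestamp if timestamp is not None else _dt.datetime.now()
    return (
        f"{participant_id}_OSARI_{ts.year:04d}_{_MONTHS[ts.month - 1]}_"
        f"{ts.day}_{ts.hour:02d}{ts.minute:02d}.txt"
    )


def parse_filename(name: str) -> tuple[str, _dt.datetime]:
    """Inverse of :func:`build_filename` (accepts a trailing ``.txt``)."""
    stem = name[:-4] if name.endswith(".txt") else name
    m = _NAME_RE.match(stem)
    if m is None:
        raise ValueError(f"{name!r} does not match the ID_OSARI_yyyy_month_d_hhmm pattern")
    month = _MONTHS.index(m["month"]) + 1
    hm = m["hm"]
    return m["id"], _dt.datetime(int(m["year"]), month, int(m["day"]), int(hm[:2]), int(hm[2:]))


# ---------------------------------------------------------------------------
# condition tables (trialType / fixedStopTime rows)

def write_condition_table(spec: BlockSpec, path: str | Path) -> Path:
    """Write a block as a condition table: one row per trial, columns
    ``trialType`` ('go'/'stop') and ``fixedStopTime`` (ms, NaN on go rows)."""
    signals = (
        spec.signal_order
        if spec.signal_order is not None
        else [GO] * spec.n_go + [STOP] * spec.n_stop
    )
    stop_iter = iter(spec.fixed_stop_times or ())
    rows = []
    for s in signals:
        fixed = next(stop_iter, math.nan) if s == STOP else math.nan
        rows.append(("stop" if s == STOP else "go", fixed))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("trialType fixedStopTime\n")
        for kind, fixed in rows:
            fh.write(f"{kind} {_fmt(fixed)}\n")
    return path


def read_condition_table(path: str | Path, label: str = "testMixed") -> BlockSpec:
    """Read a condition table into a :class:`BlockSpec`, preserving row order."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if "trialType" not in df.columns:
        raise TrialFileError(f"{Path(path).name}: condition table needs a 'trialType' column")
    kinds = df["trialType"].str.lower()
    bad = kinds[~kinds.isin(["go", "stop"])]
    if len(bad):
        raise TrialFileError(f"row {bad.index[0] + 1}: trialType must be 'go' or 'stop'")
    signals = tuple(STOP if k == "stop" else GO for k in kinds)
    fixed = None
    if "fixedStopTime" in df.columns:
        vals = pd.to_numeric(df["fixedStopTime"].replace("NaN", "nan"), errors="coerce")
        stops = vals[kinds == "stop"]
        if stops.notna().all() and len(stops):
            fixed = tuple(float(v) for v in stops)
    return BlockSpec(
        label=label,
        n_go=int((kinds == "go").sum()),
        n_stop=int((kinds == "stop").sum()),
        fixed_stop_times=fixed,
        signal_order=signals,
    )


# ---------------------------------------------------------------------------
# cohort manifest (true generative parameters, for recovery studies)

_MANIFEST_COLS = [
    "id", "go_mean", "go_sd", "ssrt_mean", "ssrt_sd",
    "p_trigger_failure", "p_start_interval_lift",
]


def write_manifest(rows: Iterable[tuple[str, "ParticipantParams"]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(" ".join(_MANIFEST_COLS) + "\n")
        for pid, pp in rows:
            fh.write(
                f"{pid} {pp.go_mean:g} {pp.go_sd:g} {pp.ssrt_mean:g} {pp.ssrt_sd:g} "
                f"{pp.p_trigger_failure:g} {pp.p_start_interval_lift:g}\n"
            )
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing:
        raise TrialFileError(f"manifest missing column(s) {missing}")
    return df
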