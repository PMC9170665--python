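"""Per-participant and batch analysis of stop-signal task data.

Implements the standard nonparametric workflow for the anticipated-response
variant: go-trial descriptives with feedback-band proportions, stop-trial
descriptives, the empirical inhibition function p(respond | SSD), the
integration-with-replacement SSRT estimator, and the proactive-inhibition
contrast between the go-only test block and the mixed test blocks.

SSRT (integration method with replacement for omissions): append one
``trial_duration`` per go omission to the go-RT sample, sort ascending, take
the RT at 1-based rank ``ceil(p * N)`` where ``p = P(respond | signal)`` and
``N`` is the augmented sample size, and subtract the mean SSD.  Test-phase
trials only feed the estimate; practice performance is recorded but never
carried over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import data_io
from .task_model import GO, STOP, TaskParameters, classify_go_feedback

__all__ = [
    "GoMetrics",
    "StopMetrics",
    "ProactiveMetrics",
    "compute_go_metrics",
    "p_respond_given_signal",
    "estimate_ssrt_integration",
    "inhibition_function",
    "proactive_inhibition",
    "analyze_participant",
    "analyze_batch",
    "visualize_participant",
    "render_participant_figure",
]

BANDS = ("green", "yellow", "orange", "red")


@dataclass(frozen=True)
class GoMetrics:
    """Go-trial summary: RT moments over responded trials, omission count and
    the proportion of trials in each feedback band (omissions excluded from
    bands; band + omission proportions sum to 1)."""

    n_go: int
    mean_rt: float
    sd_rt: float
    n_omissions: int
    band_proportions: dict[str, float]


@dataclass(frozen=True)
class StopMetrics:
    """Stop-trial summary, including the integration-method SSRT (seconds).

    ``ssrt`` is NaN (with ``ssrt_flag`` saying why) when the estimator is
    undefined — e.g. a participant who never responded on a stop trial.
    """

    n_stop: int
    p_respond_signal: float
    mean_ssd: float
    mean_signal_respond_rt: float
    ssrt: float
    ssrt_flag: str = "ok"


@dataclass(frozen=True)
class ProactiveMetrics:
    """Go-RT slowing in mixed blocks relative to the go-only test block."""

    delta_mean_rt: float
    delta_sd_rt: float


def _go_trials(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["signal"] == GO]


def _stop_trials(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["signal"] == STOP]


def _test_phase(df: pd.DataFrame) -> pd.DataFrame:
    """Drop practice blocks (labels starting with 'practice')."""
    return df[~df["trialType"].astype(str).str.startswith("practice")]


def compute_go_metrics(trials: pd.DataFrame, params: TaskParameters | None = None) -> GoMetrics:
    """Summarise go trials: mean/SD of responded RTs, omissions, feedback bands.

    An omission is a go trial with no key lift before the bar filled
    (response = 0).  With no responded trials, the RT moments are NaN.
    """
    params = params if params is not None else TaskParameters()
    go = _go_trials(trials)
    if len(go) == 0:
        raise ValueError("no go trials to analyze")
    responded = go[go["response"] == 1]
    rts = responded["rt"].to_numpy(float)
    n_om = int(len(go) - len(responded))
    counts = dict.fromkeys(BANDS, 0)
    for rt in rts:
        counts[classify_go_feedback(float(rt), params)] += 1
    props = {b: counts[b] / len(go) for b in BANDS}
    return GoMetrics(
        n_go=int(len(go)),
        mean_rt=float(np.mean(rts)) if len(rts) else math.nan,
        sd_rt=float(np.std(rts, ddof=1)) if len(rts) > 1 else (0.0 if len(rts) else math.nan),
        n_omissions=n_om,
        band_proportions=props,
    )


def p_respond_given_signal(trials: pd.DataFrame) -> float:
    """Failed stops / all stop trials — the empirical P(respond | signal)."""
    stops = _stop_trials(trials)
    if len(stops) == 0:
        raise ValueError("no stop trials to analyze")
    return float(stops["response"].mean())


def estimate_ssrt_integration(
    go_rts: Sequence[float],
    n_go_omissions: int,
    p_respond: float,
    mean_ssd: float,
    params: TaskParameters | None = None,
) -> float:
    """Integration-method SSRT with replacement of omissions (seconds).

    Each go omission is replaced by the trial duration (the slowest possible
    response); the augmented RTs are sorted and the value at 1-based rank
    ``ceil(p_respond * N)`` is the finishing time the stop process must beat,
    so SSRT = that quantile − mean SSD.  Undefined for ``p_respond = 0``
    (returns NaN: no stop trial ever escaped inhibition).
    """
    params = params if params is not None else TaskParameters()
    rts = np.asarray(list(go_rts), dtype=float)
    rts = rts[np.isfinite(rts)]
    if len(rts) == 0:
        raise ValueError("need at least one finite go RT")
    if not 0 <= p_respond <= 1:
        raise ValueError("p_respond must lie in [0, 1]")
    if p_respond == 0:
        return math.nan
    augmented = np.sort(np.concatenate([rts, np.full(n_go_omissions, params.trial_duration)]))
    n = len(augmented)
    rank = math.ceil(p_respond * n)
    quantile_rt = float(augmented[min(rank, n) - 1])
    return quantile_rt - mean_ssd


def inhibition_function(trials: pd.DataFrame, bin_width: float = 0.05) -> pd.DataFrame:
    """Empirical p(respond | SSD): stop trials grouped into SSD bins.

    Returns a frame with columns ``ssd_bin`` (bin centre, s), ``n_trials``
    and ``p_respond``, one row per nonempty bin, ascending in SSD.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    stops = _stop_trials(trials)
    if len(stops) == 0:
        raise ValueError("no stop trials to analyze")
    ssd = stops["ssd"].to_numpy(float)
    resp = stops["response"].to_numpy(float)
    bins = np.floor(ssd / bin_width).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        rows.append(
            {
                "ssd_bin": (b + 0.5) * bin_width,
                "n_trials": int(sel.sum()),
                "p_respond": float(resp[sel].mean()),
            }
        )
    return pd.DataFrame(rows, columns=["ssd_bin", "n_trials", "p_respond"])


def proactive_inhibition(
    test_go_trials: pd.DataFrame, mixed_go_trials: pd.DataFrame
) -> ProactiveMetrics:
    """Mean and SD go-RT differences, mixed − go-only (positive = slowing)."""
    a = _go_trials(test_go_trials)
    b = _go_trials(mixed_go_trials)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both trial sets must contain go trials")
    rt_a = a.loc[a["response"] == 1, "rt"].to_numpy(float)
    rt_b = b.loc[b["response"] == 1, "rt"].to_numpy(float)
    if len(rt_a) == 0 or len(rt_b) == 0:
        raise ValueError("both trial sets must contain responded go trials")
    sd_a = float(np.std(rt_a, ddof=1)) if len(rt_a) > 1 else 0.0
    sd_b = float(np.std(rt_b, ddof=1)) if len(rt_b) > 1 else 0.0
    return ProactiveMetrics(
        delta_mean_rt=float(np.mean(rt_b) - np.mean(rt_a)),
        delta_sd_rt=sd_b - sd_a,
    )


def compute_stop_metrics(
    trials: pd.DataFrame, params: TaskParameters | None = None
) -> StopMetrics:
    """Stop-trial descriptives + SSRT from the test-phase trials of a session.

    Go RTs, omissions, P(respond|signal) and the mean SSD all come from the
    mixed test blocks (practice excluded); the go-only test block feeds only
    the proactive contrast, never the SSRT.
    """
    params = params if params is not None else TaskParameters()
    test = _test_phase(trials)
    mixed = test[test["trialType"].astype(str) != "testGo"]
    stops = _stop_trials(mixed)
    if len(stops) == 0:
        raise ValueError("no test-phase stop trials to analyze")
    p_resp = float(stops["response"].mean())
    mean_ssd = float(stops["ssd"].astype(float).mean())
    failed = stops[stops["response"] == 1]
    mean_srrt = float(failed["rt"].astype(float).mean()) if len(failed) else math.nan

    go = _go_trials(mixed)
    go_rts = go.loc[go["response"] == 1, "rt"].to_numpy(float)
    n_om = int((go["response"] == 0).sum())
    if p_resp == 0:
        ssrt, flag = math.nan, "p_respond_zero"
    elif len(go_rts) == 0:
        ssrt, flag = math.nan, "no_go_rts"
    else:
        ssrt = estimate_ssrt_integration(go_rts, n_om, p_resp, mean_ssd, params)
        flag = "ok"
    return StopMetrics(
        n_stop=int(len(stops)),
        p_respond_signal=p_resp,
        mean_ssd=mean_ssd,
        mean_signal_respond_rt=mean_srrt,
        ssrt=ssrt,
        ssrt_flag=flag,
    )


def analyze_participant(
    trials: pd.DataFrame, params: TaskParameters | None = None
) -> pd.Series:
    """One flat metrics row for a participant session.

    Combines go descriptives (test-phase go trials), stop descriptives with
    SSRT, and — when a go-only test block is present — the proactive
    contrast.  Mirrors a batch-analysis row of the companion R workflow.
    """
    params = params if params is not None else TaskParameters()
    test = _test_phase(trials)
    mixed = test[test["trialType"].astype(str) != "testGo"]
    test_go_block = test[test["trialType"].astype(str) == "testGo"]

    gm = compute_go_metrics(_go_trials(mixed) if len(_go_trials(mixed)) else test, params)
    row: dict[str, object] = {
        "id": trials["id"].iloc[0] if "id" in trials and len(trials) else "",
        "n_go": gm.n_go,
        "go_mean_rt": gm.mean_rt,
        "go_sd_rt": gm.sd_rt,
        "n_go_omissions": gm.n_omissions,
    }
    for b in BANDS:
        row[f"prop_{b}"] = gm.band_proportions[b]

    try:
        sm = compute_stop_metrics(trials, params)
        row.update(
            n_stop=sm.n_stop,
            p_respond_signal=sm.p_respond_signal,
            mean_ssd=sm.mean_ssd,
            mean_signal_respond_rt=sm.mean_signal_respond_rt,
            ssrt=sm.ssrt,
            ssrt_flag=sm.ssrt_flag,
        )
    except ValueError:
        row.update(
            n_stop=0, p_respond_signal=math.nan, mean_ssd=math.nan,
            mean_signal_respond_rt=math.nan, ssrt=math.nan, ssrt_flag="no_stop_trials",
        )

    if len(test_go_block) and len(_go_trials(mixed)):
        pm = proactive_inhibition(test_go_block, mixed)
        row["proactive_delta_mean_rt"] = pm.delta_mean_rt
        row["proactive_delta_sd_rt"] = pm.delta_sd_rt
    else:
        row["proactive_delta_mean_rt"] = math.nan
        row["proactive_delta_sd_rt"] = math.nan
    return pd.Series(row)


def analyze_batch(
    paths: Sequence[str | Path],
    dialect: str = "OSARI",
    params: TaskParameters | None = None,
    *,
    on_error: str = "warn",
) -> tuple[pd.DataFrame, list[str]]:
    """Analyze many trial files into one metrics table (one row each).

    Unparseable files are skipped and reported in the returned warning list
    (``on_error='raise'`` re-raises instead), so one corrupt export does not
    sink a batch.
    """
    rows, warnings = [], []
    for p in paths:
        try:
            df = data_io.read_trials(p, dialect)
            rows.append(analyze_participant(df, params))
        except Exception as exc:  # noqa: BLE001 - batch robustness by contract
            if on_error == "raise":
                raise
            warnings.append(f"{Path(p).name}: {exc}")
    table = pd.DataFrame(rows) if rows else pd.DataFrame()
    return table, warnings


# ---------------------------------------------------------------------------
# plot-data bundles (six panels: go descriptives, RT by trial, RT density,
# stop descriptives, SSD by trial, inhibition function)

def visualize_participant(
    trials: pd.DataFrame,
    params: TaskParameters | None = None,
    bin_width: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Build the six per-participant plot tables.

    Keys: ``go_descriptives``, ``rt_by_trial``, ``rt_density``,
    ``stop_descriptives``, ``ssd_by_trial``, ``inhibition_function``.
    Rendering to an image is a thin optional layer over these tables
    (:func:`render_participant_figure`).  A session with no stop trials
    yields empty stop-side tables.
    """
    params = params if params is not None else TaskParameters()
    if len(trials) == 0:
        raise ValueError("empty session")
    df = trials.reset_index(drop=True).copy()
    df["trial_seq"] = np.arange(1, len(df) + 1)
    # correct = response made on go, response withheld on stop
    df["correct"] = np.where(df["signal"] == GO, df["response"] == 1, df["response"] == 0)

    gm = compute_go_metrics(df, params)
    go_desc = pd.DataFrame(
        [
            {
                "n_go": gm.n_go,
                "mean_rt": gm.mean_rt,
                "sd_rt": gm.sd_rt,
                "n_omissions": gm.n_omissions,
                **{f"prop_{b}": gm.band_proportions[b] for b in BANDS},
            }
        ]
    )
    rt_by_trial = df[["trial_seq", "trialType", "block", "trial", "signal", "rt", "correct"]].copy()

    responded = df[df["rt"].notna()]
    rt_density = pd.DataFrame(
        {
            "rt": responded["rt"].to_numpy(float),
            "trial_class": np.where(responded["signal"] == GO, "go", "signal_respond"),
        }
    ).sort_values("rt", kind="stable", ignore_index=True)

    stops = _stop_trials(df)
    if len(stops):
        sm_cols: dict[str, object]
        try:
            sm = compute_stop_metrics(df, params)
            sm_cols = {
                "n_stop": sm.n_stop,
                "p_respond_signal": sm.p_respond_signal,
                "mean_ssd": sm.mean_ssd,
                "mean_signal_respond_rt": sm.mean_signal_respond_rt,
                "ssrt": sm.ssrt,
            }
        except ValueError:  # stop trials only in practice
            sm_cols = {
                "n_stop": int(len(stops)),
                "p_respond_signal": float(stops["response"].mean()),
                "mean_ssd": float(stops["ssd"].mean()),
                "mean_signal_respond_rt": math.nan,
                "ssrt": math.nan,
            }
        stop_desc = pd.DataFrame([sm_cols])
        ssd_by_trial = stops[["trial_seq", "trialType", "block", "trial", "ssd", "correct"]].copy()
        inhib = inhibition_function(df, bin_width)
    else:
        stop_desc = pd.DataFrame()
        ssd_by_trial = pd.DataFrame()
        inhib = pd.DataFrame()

    return {
        "go_descriptives": go_desc,
        "rt_by_trial": rt_by_trial,
        "rt_density": rt_density,
        "stop_descriptives": stop_desc,
        "ssd_by_trial": ssd_by_trial,
        "inhibition_function": inhib,
    }


def render_participant_figure(bundle: dict[str, pd.DataFrame], path: str | Path) -> Path:
    """Render the six panel tables to one figure file (optional layer)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(15, 8))
    (ax_a, ax_b, ax_c), (ax_d, ax_e, ax_f) = axes

    def _table_panel(ax, frame: pd.DataFrame, title: str) -> None:
        ax.axis("off")
        ax.set_title(title)
        if len(frame):
            text = "\n".join(
                f"{k}: {v:.3f}" if isinstance(v, float) else f"{k}: {v}"
                for k, v in frame.iloc[0].items()
            )
            ax.text(0.05, 0.95, text, va="top", family="monospace", fontsize=9)

    _table_panel(ax_a, bundle["go_descriptives"], "Go descriptives")
    _table_panel(ax_d, bundle["stop_descriptives"], "Stop descriptives")

    rbt = bundle["rt_by_trial"]
    for sig, marker in ((GO, "s"), (STOP, "o")):
        sel = rbt[(rbt["signal"] == sig) & rbt["rt"].notna()]
        colors = np.where(sel["correct"], "tab:blue", "tab:red")
        ax_b.scatter(sel["trial_seq"], sel["rt"], marker=marker, c=colors, s=12)
    ax_b.set_xlabel("Trial")
    ax_b.set_ylabel("RT (s)")
    ax_b.set_title("RT by trial")

    dens = bundle["rt_density"]
    for cls, color in (("go", "tab:blue"), ("signal_respond", "tab:red")):
        vals = dens.loc[dens["trial_class"] == cls, "rt"]
        if len(vals) > 1:
            ax_c.hist(vals, bins=20, density=True, alpha=0.5, color=color, label=cls)
    ax_c.set_xlabel("RT (s)")
    ax_c.set_ylabel("Density")
    ax_c.set_title("RT distributions")
    ax_c.legend(fontsize=8)

    sbt = bundle["ssd_by_trial"]
    if len(sbt):
        ax_e.plot(sbt["trial_seq"], sbt["ssd"], "o-", ms=4)
    ax_e.set_xlabel("Trial")
    ax_e.set_ylabel("SSD (s)")
    ax_e.set_title("SSD by trial")

    inhib = bundle["inhibition_function"]
    if len(inhib):
        ax_f.plot(inhib["ssd_bin"], inhib["p_respond"], "o-")
        ax_f.set_ylim(-0.05, 1.05)
    ax_f.set_xlabel("SSD (s)")
    ax_f.set_ylabel("p(respond | signal)")
    ax_f.set_title("Inhibition function")

    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
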