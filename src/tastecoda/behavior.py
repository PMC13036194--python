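"""Lickometer analytics.

Per-stimulus lick summaries, conditioning-session drinking metrics,
forced/unforced splits on extinction days, simple paired comparisons, and
the per-trial response-magnitude-versus-licks regression.  A lick belongs
to a trial when its timestamp falls within [onset, onset + 5 s); licks
outside every trial window are logged and dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TRIAL_S = 5.0


def count_licks_per_trial(
    licks: pd.DataFrame, trials: pd.DataFrame, trial_s: float = TRIAL_S
) -> pd.DataFrame:
    """Per-trial lick counts for one session, validated against the trial
    windows.  Returns the trial table plus a ``count`` column; licks
    falling outside their trial's window are dropped with a log entry."""
    counts = []
    n_dropped = 0
    for trial in trials.itertuples():
        t = licks.loc[licks["trial_id"] == trial.trial_id, "lick_time_s"].to_numpy()
        in_win = (t >= trial.onset_s) & (t < trial.onset_s + trial_s)
        n_dropped += int((~in_win).sum())
        counts.append(int(in_win.sum()))
    orphans = int((~licks["trial_id"].isin(trials["trial_id"])).sum())
    if n_dropped or orphans:
        logger.warning("dropped %d licks outside trial windows", n_dropped + orphans)
    out = trials.copy()
    out["count"] = counts
    return out


def lick_summary(
    sessions: list[tuple[str, str, str, pd.DataFrame, pd.DataFrame]],
    trial_s: float = TRIAL_S,
) -> pd.DataFrame:
    """Per animal/day/stimulus lick summary.

    ``sessions`` holds ``(animal, group, day, trials, licks)`` tuples for
    non-conditioning days.  Forced trials (the NaCl-Force series) carry a
    distinct stimulus label and therefore summarize separately.  Stimuli
    without trials on a day are simply absent, never zero rows.
    """
    rows = []
    for animal, group, day, trials, licks in sessions:
        counted = count_licks_per_trial(licks, trials, trial_s)
        for (stim, forced), sub in counted.groupby(["stimulus", "forced"]):
            rows.append({
                "animal": animal, "group": group, "day": day, "stimulus": stim,
                "forced": bool(forced), "mean_licks": float(sub["count"].mean()),
                "n_trials": len(sub), "total_licks": int(sub["count"].sum()),
            })
    return pd.DataFrame(rows)


def conditioning_metrics(
    licks: pd.DataFrame,
    session_minutes: float = 20.0,
    cap_licks: int = 1000,
) -> dict:
    """Drinking metrics for one conditioning session.

    Returns first-minute licks, licks per minute over the session, and
    the time (minutes) at which the ``cap_licks``-th lick occurred — None
    when the cap was never reached.
    """
    t = np.sort(licks["lick_time_s"].to_numpy())
    first_minute = int((t < 60.0).sum())
    licks_per_min = float(len(t) / session_minutes)
    minutes_to_cap = float(t[cap_licks - 1] / 60.0) if len(t) >= cap_licks else None
    return {
        "total_licks": int(len(t)),
        "first_minute_licks": first_minute,
        "licks_per_min": licks_per_min,
        "minutes_to_cap": minutes_to_cap,
    }


def response_vs_licks(
    trial_responses: pd.DataFrame,
    lick_counts: pd.DataFrame,
) -> tuple[dict, pd.DataFrame]:
    """OLS regression of per-trial mean response against lick count.

    ``trial_responses`` is the trial-level response table (one row per
    cell x trial); responses are averaged over cells within each trial,
    then merged with per-trial lick counts on (animal, day, trial_id) and
    pooled over animals and days.  Returns the fit (slope, intercept,
    R^2, r, p) and the per-point table.
    """
    per_trial = (trial_responses
                 .groupby(["animal", "day", "trial_id", "stimulus"], as_index=False)
                 ["delta_plus"].mean()
                 .rename(columns={"delta_plus": "mean_response"}))
    pts = per_trial.merge(
        lick_counts[["animal", "day", "trial_id", "count"]],
        on=["animal", "day", "trial_id"], how="inner")
    if len(pts) < 3:
        raise ValueError("need at least 3 trial points for regression")
    if (np.ptp(pts["count"].to_numpy()) == 0
            or np.ptp(pts["mean_response"].to_numpy()) == 0):
        fit = {"slope": 0.0, "intercept": float(pts["mean_response"].mean()),
               "r_squared": 0.0, "r": None, "p": None, "n": len(pts)}
        return fit, pts
    res = stats.linregress(pts["count"], pts["mean_response"])
    fit = {"slope": float(res.slope), "intercept": float(res.intercept),
           "r_squared": float(res.rvalue ** 2), "r": float(res.rvalue),
           "p": float(res.pvalue), "n": len(pts)}
    return fit, pts


def paired_comparison(pre: np.ndarray, post: np.ndarray) -> dict:
    """Classical paired t-test on post - pre differences, with Cohen's d
    of the differences.  Zero-variance differences yield a null p with a
    flag rather than an error."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 values")
    diff = post - pre
    sd = diff.std(ddof=1)
    if sd == 0:
        return {"t": None, "p": None, "df": pre.size - 1,
                "cohens_d": None, "mean_diff": float(diff.mean()),
                "zero_variance": True}
    t, p = stats.ttest_rel(post, pre)
    return {"t": float(t), "p": float(p), "df": pre.size - 1,
            "cohens_d": float(diff.mean() / sd), "mean_diff": float(diff.mean()),
            "zero_variance": False}
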