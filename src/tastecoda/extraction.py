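"""Trial-aligned response extraction.

Turns trace matrices plus trial/lick tables into per-trial response
values, responsiveness calls at the +/-3 SD criterion, and per-day
averaged response tables restricted to cells tracked on all days.

Conventions: frames are 0-based, windows half-open ``[start, end)``,
times in seconds are converted to frames by ``floor(t * frame_rate)``.
The per-trial response value is computed against the 5-s window starting
at the trial's first lick (falling back to the trial onset on zero-lick
trials), with the baseline taken from the 5 s immediately before it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import CONDITIONING_LABEL

logger = logging.getLogger(__name__)

SD_CRITERION = 3.0
WINDOW_S = 5.0
_SD_FLOOR_REL = 1e-6


@dataclass
class SessionData:
    """One animal x one day of a cohort."""

    animal_id: str
    day: str
    day_kind: str
    group: str
    traces: np.ndarray  # cells x frames
    frame_rate: float
    trials: pd.DataFrame  # trial_id, stimulus, onset_s, block, forced
    licks: pd.DataFrame  # trial_id, lick_time_s
    global_cell_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        ids = np.asarray(self.global_cell_ids)
        if len(np.unique(ids)) != len(ids):
            raise ValueError("global_cell_ids must be unique")
        if self.traces.shape[0] != len(ids):
            raise ValueError("trace rows must align with global_cell_ids")


@dataclass
class ResponseTable:
    """Per-trial and per-day-averaged response values.

    ``trials`` has one row per (animal, day, cell, trial) with columns
    ``delta_plus, delta_minus, baseline_sd, excited, suppressed, anchor``;
    ``averaged`` has one row per (animal, day, cell, stimulus) with the
    arithmetic means of the per-trial values and day-level excited /
    suppressed calls evaluated on the averaged response.
    """

    trials: pd.DataFrame
    averaged: pd.DataFrame
    dropped_trials: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_both_flagged: int = 0


def align_trial_window(
    trial: pd.Series,
    licks: pd.DataFrame,
    frame_rate: float,
    n_frames: int | None = None,
) -> tuple[tuple[int, int], tuple[int, int], str]:
    """Baseline and response frame spans for one trial.

    The response span covers the 5 s from the trial's first lick; the
    baseline span covers the 5 s immediately before it.  Zero-lick trials
    anchor both spans to the trial onset instead.  Returns
    ``(baseline_span, response_span, anchor)`` with half-open spans and
    ``anchor`` in ``{"lick", "onset"}``.

    Raises ``ValueError`` when a span falls outside the recording.
    """
    onset = float(trial["onset_s"])
    t = licks.loc[licks["trial_id"] == trial["trial_id"], "lick_time_s"].to_numpy()
    t = t[(t >= onset) & (t < onset + WINDOW_S)]
    if t.size:
        t0, anchor = float(t.min()), "lick"
    else:
        t0, anchor = onset, "onset"
    width = int(round(WINDOW_S * frame_rate))
    r0 = int(np.floor(t0 * frame_rate))
    baseline = (r0 - width, r0)
    response = (r0, r0 + width)
    if baseline[0] < 0 or (n_frames is not None and response[1] > n_frames):
        raise ValueError(
            f"analysis window [{baseline[0]}, {response[1]}) outside recording "
            f"for trial {trial['trial_id']}"
        )
    return baseline, response, anchor


def compute_delta(
    trace: np.ndarray,
    baseline_span: tuple[int, int],
    response_span: tuple[int, int],
) -> tuple[float, float, float]:
    """Max- and min-based response deltas plus the floored baseline SD.

    ``delta_plus = max(response) - mean(baseline)`` and ``delta_minus =
    min(response) - mean(baseline)``.  The baseline SD (sample SD) is
    floored at 1e-6 of the trace's dynamic range so noiseless synthetic
    traces cannot produce a zero criterion.
    """
    b = trace[slice(*baseline_span)]
    r = trace[slice(*response_span)]
    if b.size == 0 or r.size == 0:
        raise ValueError("empty analysis window")
    if np.isnan(b).any() or np.isnan(r).any():
        raise ValueError("NaN values inside analysis window")
    base_mean = float(b.mean())
    sd = float(b.std(ddof=1)) if b.size > 1 else 0.0
    dyn = float(trace.max() - trace.min())
    floor = _SD_FLOOR_REL * dyn if dyn > 0 else _SD_FLOOR_REL
    return float(r.max() - base_mean), float(r.min() - base_mean), max(sd, floor)


def classify_response(
    delta_plus: float, delta_minus: float, baseline_sd: float
) -> str:
    """Classify a response as ``excited``, ``suppressed`` or ``none``.

    The threshold is inclusive; when a window crosses both thresholds the
    excited call wins (callers count these dual-threshold events).
    """
    if baseline_sd <= 0:
        raise ValueError("baseline_sd must be positive after flooring")
    if delta_plus >= SD_CRITERION * baseline_sd:
        return "excited"
    if delta_minus <= -SD_CRITERION * baseline_sd:
        return "suppressed"
    return "none"


def _is_dual(delta_plus: float, delta_minus: float, baseline_sd: float) -> bool:
    return (delta_plus >= SD_CRITERION * baseline_sd
            and delta_minus <= -SD_CRITERION * baseline_sd)


def extract_session(session: SessionData, sd_scope: str = "per_trial") -> pd.DataFrame:
    """Per-trial response table for one session (tidy, one row per
    cell x trial).  Conditioning access periods are skipped.

    ``sd_scope`` selects the baseline-SD convention: ``per_trial``
    (default) uses each trial's own baseline window; ``session`` pools all
    baseline windows of a cell across the session's trials and applies
    that single SD to every trial's classification.
    """
    if sd_scope not in ("per_trial", "session"):
        raise ValueError(f"unknown sd_scope {sd_scope!r}")
    rows = []
    dropped = []
    baselines: dict[int, list[np.ndarray]] = {}
    n_frames = session.traces.shape[1]
    for _, trial in session.trials.iterrows():
        if trial["stimulus"] == CONDITIONING_LABEL:
            continue
        try:
            bspan, rspan, anchor = align_trial_window(
                trial, session.licks, session.frame_rate, n_frames
            )
        except ValueError as err:
            logger.warning("%s/%s: dropping trial %s (%s)",
                           session.animal_id, session.day, trial["trial_id"], err)
            dropped.append({"animal": session.animal_id, "day": session.day,
                            "trial_id": trial["trial_id"], "reason": str(err)})
            continue
        for row_idx, cell in enumerate(session.global_cell_ids):
            try:
                dp, dm, sd = compute_delta(session.traces[row_idx], bspan, rspan)
            except ValueError as err:
                raise ValueError(
                    f"{session.animal_id}/{session.day} cell {cell} "
                    f"trial {trial['trial_id']}: {err}"
                ) from err
            cls = classify_response(dp, dm, sd)
            rows.append({
                "animal": session.animal_id, "group": session.group,
                "day": session.day, "cell": int(cell),
                "trial_id": int(trial["trial_id"]), "stimulus": trial["stimulus"],
                "delta_plus": dp, "delta_minus": dm, "baseline_sd": sd,
                "class": cls, "dual": _is_dual(dp, dm, sd), "anchor": anchor,
            })
            if sd_scope == "session":
                baselines.setdefault(int(cell), []).append(
                    session.traces[row_idx, slice(*bspan)])
    trials_df = pd.DataFrame(rows)
    if sd_scope == "session" and not trials_df.empty:
        pooled_sd = {}
        for cell, chunks in baselines.items():
            pooled = np.concatenate(chunks)
            row_idx = int(np.flatnonzero(session.global_cell_ids == cell)[0])
            trace = session.traces[row_idx]
            dyn = float(trace.max() - trace.min())
            floor = _SD_FLOOR_REL * dyn if dyn > 0 else _SD_FLOOR_REL
            pooled_sd[cell] = max(float(pooled.std(ddof=1)), floor)
        trials_df["baseline_sd"] = trials_df["cell"].map(pooled_sd)
        trials_df["class"] = [
            classify_response(dp, dm, sd) for dp, dm, sd in
            zip(trials_df["delta_plus"], trials_df["delta_minus"],
                trials_df["baseline_sd"])]
        trials_df["dual"] = [
            _is_dual(dp, dm, sd) for dp, dm, sd in
            zip(trials_df["delta_plus"], trials_df["delta_minus"],
                trials_df["baseline_sd"])]
    trials_df.attrs["dropped"] = dropped
    return trials_df


def average_responses(trials_df: pd.DataFrame) -> pd.DataFrame:
    """Per-day averaged responses: one row per (animal, day, cell,
    stimulus), the mean of that day's per-trial values, with excited /
    suppressed calls re-evaluated on the averaged deltas against the mean
    baseline SD."""
    if trials_df.empty:
        return pd.DataFrame(columns=[
            "animal", "group", "day", "cell", "stimulus",
            "delta_plus", "delta_minus", "baseline_sd",
            "n_trials", "excited", "suppressed"])
    grouped = (
        trials_df
        .groupby(["animal", "group", "day", "cell", "stimulus"], as_index=False)
        .agg(delta_plus=("delta_plus", "mean"),
             delta_minus=("delta_minus", "mean"),
             baseline_sd=("baseline_sd", "mean"),
             n_trials=("trial_id", "size"))
    )
    thr = SD_CRITERION * grouped["baseline_sd"]
    grouped["excited"] = grouped["delta_plus"] >= thr
    grouped["suppressed"] = (grouped["delta_minus"] <= -thr) & ~grouped["excited"]
    return grouped


def build_response_table(sessions: list[SessionData],
                         sd_scope: str = "per_trial") -> ResponseTable:
    """Extract and average every session into one ResponseTable."""
    parts = [extract_session(s, sd_scope=sd_scope) for s in sessions]
    dropped = [d for p in parts for d in p.attrs.get("dropped", [])]
    trials_df = pd.concat([p for p in parts if not p.empty], ignore_index=True) \
        if any(not p.empty for p in parts) else pd.DataFrame()
    n_dual = int(trials_df["dual"].sum()) if not trials_df.empty else 0
    if n_dual:
        logger.info("%d trial windows crossed both thresholds (classified excited)",
                    n_dual)
    return ResponseTable(
        trials=trials_df,
        averaged=average_responses(trials_df),
        dropped_trials=pd.DataFrame(dropped),
        n_both_flagged=n_dual,
    )


def filter_tracked(sessions: list[SessionData]) -> tuple[list[SessionData], pd.DataFrame]:
    """Restrict each animal's sessions to cells present on all of its days.

    Returns the filtered sessions plus a per-animal report of tracked-cell
    counts.  Animals with zero tracked cells are dropped with a warning.
    """
    by_animal: dict[str, list[SessionData]] = {}
    for s in sessions:
        by_animal.setdefault(s.animal_id, []).append(s)
    out: list[SessionData] = []
    report = []
    for animal, sess in by_animal.items():
        tracked = set(np.asarray(sess[0].global_cell_ids).tolist())
        for s in sess[1:]:
            tracked &= set(np.asarray(s.global_cell_ids).tolist())
        report.append({"animal": animal, "n_tracked": len(tracked),
                       "n_days": len(sess)})
        if not tracked:
            logger.warning("animal %s has no cells tracked on all %d days; dropped",
                           animal, len(sess))
            continue
        keep = sorted(tracked)
        for s in sess:
            ids = np.asarray(s.global_cell_ids)
            idx = [int(np.flatnonzero(ids == c)[0]) for c in keep]
            out.append(SessionData(
                animal_id=s.animal_id, day=s.day, day_kind=s.day_kind,
                group=s.group, traces=s.traces[idx], frame_rate=s.frame_rate,
                trials=s.trials, licks=s.licks,
                global_cell_ids=np.array(keep),
            ))
    return out, pd.DataFrame(report)


def summarize_responses(table: ResponseTable) -> pd.DataFrame:
    """Per-animal, per-day response summaries.

    One row per (animal, day, stimulus) plus a pooled ``all`` row:
    fraction of tracked cells perturbed (excited or suppressed on the
    day-averaged response; the pooled row counts cell-stimulus pairs),
    mean magnitude over significantly excited responses, and mean
    magnitude over significantly suppressed responses.  Magnitudes are
    null (NaN) when no cell qualifies.
    """
    avg = table.averaged
    rows = []
    for (animal, group, day), sub in avg.groupby(["animal", "group", "day"]):
        scopes = [(stim, s) for stim, s in sub.groupby("stimulus")]
        scopes.append(("all", sub))
        for stim, s in scopes:
            n_cells = len(s)
            perturbed = int((s["excited"] | s["suppressed"]).sum())
            exc = s.loc[s["excited"], "delta_plus"]
            sup = s.loc[s["suppressed"], "delta_minus"]
            rows.append({
                "animal": animal, "group": group, "day": day, "stimulus": stim,
                "n_cells": n_cells,
                "fraction_perturbed": perturbed / n_cells if n_cells else np.nan,
                "mean_excited_magnitude": float(exc.mean()) if len(exc) else np.nan,
                "mean_suppressed_magnitude": float(sup.mean()) if len(sup) else np.nan,
            })
    return pd.DataFrame(rows)


# -- cohort directory reading ------------------------------------------


def load_cohort_dir(path: str | Path) -> list[SessionData]:
    """Load all sessions from a cohort directory written by the generator."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    frame_rate = float(manifest["frame_rate"])
    kinds = {d["name"]: d["kind"] for d in manifest["days"]}
    sessions = []
    for group, animals in manifest["groups"].items():
        for animal in animals:
            for day in kinds:
                day_dir = path / animal / day
                if not day_dir.exists():
                    continue
                traces = pd.read_csv(day_dir / "traces.csv", index_col="cell")
                sessions.append(SessionData(
                    animal_id=animal, day=day, day_kind=kinds[day], group=group,
                    traces=traces.to_numpy(), frame_rate=frame_rate,
                    trials=pd.read_csv(day_dir / "trials.csv"),
                    licks=pd.read_csv(day_dir / "licks.csv"),
                    global_cell_ids=traces.index.to_numpy(),
                ))
    return sessions
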