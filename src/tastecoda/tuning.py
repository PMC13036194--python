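"""Breadth-of-tuning entropy and best-stimulus analyses.

Entropy follows the taste-literature convention H = -K * sum(p_i *
log10(p_i)) with K = 1/log10(n); for the four basic tastes K = 1.661 and
H runs from 0 (responds to a single stimulus) to 1 (equal responses to
all).  Only positive responses enter the proportions p_i; raw values are
retained everywhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import AVERSIVE_LABEL, BASIC_TASTES, CS_LABEL, UNIT_LABELS

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_DAY = "pretest2"


@dataclass
class TuningProfile:
    cell: int
    day: str
    responses: np.ndarray  # mean response per basic taste, panel order
    entropy: float
    best_stimulus: str


def entropy(responses: np.ndarray | list[float]) -> float:
    """Breadth-of-tuning entropy of one response vector.

    Negative entries are clipped to zero before normalizing; a vector
    with no positive entry has undefined entropy (NaN).  0*log(0) counts
    as 0.
    """
    v = np.clip(np.asarray(responses, dtype=float), 0.0, None)
    total = v.sum()
    if total <= 0 or v.size < 2:
        return float("nan")
    p = v / total
    k = 1.0 / np.log10(v.size)
    nz = p[p > 0]
    return float(-k * np.sum(nz * np.log10(nz)))


def _pivot_basic(averaged: pd.DataFrame, day: str) -> pd.DataFrame:
    """(animal, cell) x basic-taste matrix of day-averaged responses."""
    sub = averaged[(averaged["day"] == day)
                   & (averaged["stimulus"].isin(BASIC_TASTES))]
    wide = sub.pivot_table(index=["animal", "cell"], columns="stimulus",
                           values="delta_plus")
    missing = [s for s in BASIC_TASTES if s not in wide.columns]
    if missing:
        raise ValueError(f"day {day!r} is missing basic tastes {missing}")
    return wide[list(BASIC_TASTES)]


def tuning_table(averaged: pd.DataFrame, days: list[str] | None = None) -> pd.DataFrame:
    """Per-cell entropy and best stimulus for each requested day.

    Cells whose basic-taste response vector has no positive entry get NaN
    entropy and are excluded from entropy means downstream.
    """
    if days is None:
        days = [d for d in averaged["day"].unique() if d != "conditioning"]
    rows = []
    for day in days:
        wide = _pivot_basic(averaged, day)
        for (animal, cell), resp in wide.iterrows():
            vec = resp.to_numpy()
            rows.append({
                "animal": animal, "day": day, "cell": cell,
                "entropy": entropy(vec),
                "best_stimulus": BASIC_TASTES[int(np.argmax(vec))],
            })
    return pd.DataFrame(rows)


def assign_best_stimulus(
    averaged: pd.DataFrame, reference_day: str = DEFAULT_REFERENCE_DAY
) -> pd.DataFrame:
    """Stimulus-best unit label per cell, from the reference day.

    The label is the argmax over the four basic-taste day-averaged
    responses; exact ties resolve to the earliest stimulus in the fixed
    panel order (the tie count is logged).  Returns columns ``animal,
    cell, best_stimulus, unit``.
    """
    wide = _pivot_basic(averaged, reference_day)
    vals = wide.to_numpy()
    best_idx = np.argmax(vals, axis=1)
    n_ties = int(np.sum((vals == vals.max(axis=1, keepdims=True)).sum(axis=1) > 1))
    if n_ties:
        logger.info("%d cells had tied best responses on %s; first-in-order wins",
                    n_ties, reference_day)
    out = wide.reset_index()[["animal", "cell"]]
    out["best_stimulus"] = [BASIC_TASTES[i] for i in best_idx]
    out["unit"] = out["best_stimulus"].map(UNIT_LABELS)
    return out


def tuning_shift_table(
    labels: pd.DataFrame,
    averaged: pd.DataFrame,
    post_day: str = "posttest1",
    stimuli: tuple[str, str] = (CS_LABEL, AVERSIVE_LABEL),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Post-conditioning responses of N-Units and Q-Units to the CS and
    to quinine, by group.

    Returns ``(summary, cells)``: the 2x2x2 (unit x stimulus x group)
    table of mean responses, and the underlying cell-level rows for
    downstream statistics.  Empty unit classes yield null means.
    """
    post = averaged[(averaged["day"] == post_day)
                    & (averaged["stimulus"].isin(stimuli))]
    cells = post.merge(labels[["animal", "cell", "unit"]], on=["animal", "cell"])
    cells = cells[cells["unit"].isin(["N-Unit", "Q-Unit"])]
    grid = [
        {"group": g, "unit": u, "stimulus": s}
        for g in sorted(averaged["group"].unique())
        for u in ("N-Unit", "Q-Unit") for s in stimuli
    ]
    summary = pd.DataFrame(grid)
    means = (cells.groupby(["group", "unit", "stimulus"])["delta_plus"]
             .agg(["mean", "size"]).reset_index()
             .rename(columns={"mean": "mean_response", "size": "n_cells"}))
    summary = summary.merge(means, on=["group", "unit", "stimulus"], how="left")
    return summary, cells
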