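"""Session trial schedules.

Test sessions present each panel stimulus once per block, in pseudorandom
order within the block, with every stimulus trial followed by a water
rinse trial.  Extinction sessions open with 12 forced CS trials (a
distinct stimulus label) and close with one randomized block.  The
conditioning session is a single access period.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    CONDITIONING_LABEL,
    FORCED_CS_LABEL,
    WATER,
    GeneratorConfig,
)

__all__ = ["build_schedule", "DAY_KINDS"]

DAY_KINDS = ("pretest", "conditioning", "posttest", "extinction")

_COLUMNS = ["trial_id", "stimulus", "onset_s", "block", "forced"]


def _rows_to_frame(rows: list[tuple[str, int, bool]], config: GeneratorConfig) -> pd.DataFrame:
    period = config.trial_s + config.iti_s
    records = [
        {
            "trial_id": i,
            "stimulus": stim,
            "onset_s": config.session_start_s + i * period,
            "block": block,
            "forced": forced,
        }
        for i, (stim, block, forced) in enumerate(rows)
    ]
    return pd.DataFrame.from_records(records, columns=_COLUMNS)


def build_schedule(
    day_kind: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Build the trial table for one session.

    Returns a DataFrame with columns ``trial_id, stimulus, onset_s, block,
    forced``.  Onsets are spaced by trial duration + ITI.
    """
    if day_kind not in DAY_KINDS:
        raise ValueError(f"unknown day_kind {day_kind!r}; expected one of {DAY_KINDS}")
    panel = list(config.stimulus_panel)
    if not panel:
        raise ValueError("stimulus panel is empty")

    rows: list[tuple[str, int, bool]] = []
    if day_kind in ("pretest", "posttest"):
        for block in range(1, config.n_blocks + 1):
            for stim in rng.permutation(panel):
                rows.append((str(stim), block, False))
                rows.append((WATER, block, False))
    elif day_kind == "extinction":
        rows.extend((FORCED_CS_LABEL, 0, True) for _ in range(12))
        for stim in rng.permutation(panel):
            rows.append((str(stim), 1, False))
            rows.append((WATER, 1, False))
    else:  # conditioning: one access period
        return pd.DataFrame.from_records(
            [{"trial_id": 0, "stimulus": CONDITIONING_LABEL, "onset_s": 0.0,
              "block": 0, "forced": True}],
            columns=_COLUMNS,
        )
    return _rows_to_frame(rows, config)
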