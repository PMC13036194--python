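"""Lickometer behavior simulation.

Per-trial lick counts follow a negative-binomial model centered on the
stimulus's palatability score, emitted as timestamps jittered around an
~8 Hz lick rhythm.  The conditioning session streams licks at a slower
rhythm until the animal's intrinsic budget, the 1,000-lick cap, or the
session clock runs out — whichever comes first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    CONDITIONING_LABEL,
    CS_LABEL,
    FORCED_CS_LABEL,
    GROUP_CTA,
    GeneratorConfig,
)

__all__ = ["simulate_licks", "effective_scores"]

_LICK_COLUMNS = ["trial_id", "lick_time_s"]


def effective_scores(
    config: GeneratorConfig, group: str, retune_strength: float
) -> dict[str, float]:
    """Palatability scores for one animal-day.

    For the CTA group on post-conditioning days the CS score is scaled
    down toward ``cta_lick_factor`` in proportion to that day's re-tuning
    strength, so behavioral aversion and neural re-tuning co-vary (and
    both relax together during extinction).
    """
    scores = dict(config.palatability_scores)
    if group == GROUP_CTA and retune_strength > 0:
        s = float(retune_strength)
        scores[CS_LABEL] *= config.cta_lick_factor * s + (1.0 - s)
    return scores


def _nb_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _rhythm_times(rng: np.random.Generator, n: int, start: float, rate_hz: float) -> np.ndarray:
    """Timestamps of ``n`` licks jittered around a fixed rhythm."""
    if n == 0:
        return np.empty(0)
    intervals = (1.0 / rate_hz) * rng.uniform(0.8, 1.2, size=n)
    return start + np.cumsum(intervals)


def simulate_licks(
    trials: pd.DataFrame,
    config: GeneratorConfig,
    group: str,
    day_kind: str,
    rng: np.random.Generator,
    retune_strength: float = 0.0,
) -> pd.DataFrame:
    """Simulate lick timestamps for every trial of one session.

    Returns a DataFrame with columns ``trial_id, lick_time_s``; timestamps
    are in session seconds and always fall inside the trial's access
    window.
    """
    if day_kind == "conditioning":
        return _conditioning_licks(trials, config, group, rng)

    scores = effective_scores(config, group, retune_strength)
    # At the rhythmic rate only so many licks fit in one 5-s trial.
    max_fit = int(config.trial_s * config.lick_rate_hz / 1.2) - 1
    records: list[pd.DataFrame] = []
    for trial in trials.itertuples():
        stim = CS_LABEL if trial.stimulus == FORCED_CS_LABEL else trial.stimulus
        if stim not in scores:
            raise KeyError(f"no palatability score for stimulus {stim!r}")
        n = min(_nb_count(rng, scores[stim], config.lick_dispersion), max_fit)
        times = _rhythm_times(rng, n, trial.onset_s + 0.2, config.lick_rate_hz)
        times = times[times < trial.onset_s + config.trial_s]
        records.append(pd.DataFrame({"trial_id": trial.trial_id, "lick_time_s": times}))
    if not records:
        return pd.DataFrame(columns=_LICK_COLUMNS)
    out = pd.concat(records, ignore_index=True)
    out["trial_id"] = out["trial_id"].astype(int)
    return out


def _conditioning_licks(
    trials: pd.DataFrame,
    config: GeneratorConfig,
    group: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    if len(trials) != 1 or trials["stimulus"].iloc[0] != CONDITIONING_LABEL:
        raise ValueError("conditioning session must contain a single access trial")
    budget_mean = config.conditioning_budget_mean[group]
    budget = _nb_count(rng, budget_mean, config.conditioning_budget_dispersion)
    n = min(budget, config.conditioning_cap_licks)
    times = _rhythm_times(rng, n, 0.5, config.conditioning_lick_hz)
    times = times[times < config.conditioning_cap_s]
    return pd.DataFrame({"trial_id": 0, "lick_time_s": times})
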