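"""Conditioned-aversion effect as cell-level re-tuning.

A configurable fraction of Q-best cells acquires sensitivity to the CS
(their CS gain is raised to the level of their quinine gain) and the same
fraction of N-best cells loses it (CS gain dropped to 5% of its original
value).  With ``magnitude_preserving`` set, all positive CS gains are then
rescaled so the pooled mean positive CS gain is conserved exactly —
population-level response magnitudes stay flat while the identity of the
responding cells changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._rng import substream
from ..labels import AVERSIVE_LABEL, CS_LABEL, GROUP_CTA
from .config import GeneratorConfig, GroundTruth
from .traces import best_labels

__all__ = ["retune_gains", "apply_cta_retuning"]

_LOSS_FACTOR = 0.05


def retune_gains(
    base: pd.DataFrame,
    best: pd.Series,
    fraction: float,
    magnitude_preserving: bool,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[int]]:
    """Return the fully re-tuned gain matrix and the affected cell indices.

    ``base`` is one animal's pre-conditioning gain matrix; ``best`` the
    pre-conditioning best-stimulus labels.  Gains for stimuli other than
    the CS are never touched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"retune fraction must lie in [0, 1], got {fraction}")
    out = base.copy()
    if fraction == 0.0:
        return out, []

    q_cells = np.flatnonzero((best == AVERSIVE_LABEL).to_numpy())
    n_cells = np.flatnonzero((best == CS_LABEL).to_numpy())
    kq = int(round(fraction * q_cells.size))
    kn = int(round(fraction * n_cells.size))
    q_sel = rng.choice(q_cells, size=kq, replace=False) if kq else np.empty(0, int)
    n_sel = rng.choice(n_cells, size=kn, replace=False) if kn else np.empty(0, int)

    cs = out[CS_LABEL].to_numpy().copy()
    cs[q_sel] = np.maximum(cs[q_sel], out[AVERSIVE_LABEL].to_numpy()[q_sel])
    cs[n_sel] *= _LOSS_FACTOR

    if magnitude_preserving:
        pre = base[CS_LABEL].to_numpy()
        pre_mass = pre[pre > 0].sum()
        post_mass = cs[cs > 0].sum()
        if post_mass > 0:
            cs[cs > 0] *= pre_mass / post_mass
    out[CS_LABEL] = cs
    return out, sorted(int(c) for c in np.concatenate([q_sel, n_sel]))


def apply_cta_retuning(truth: GroundTruth, config: GeneratorConfig) -> GroundTruth:
    """Fill in post-conditioning gains for CTA animals.

    Pre-conditioning days are left untouched, as is every control animal.
    Each post day's gains interpolate linearly between the base and the
    fully re-tuned matrix according to that day's re-tuning strength, so
    an extinction schedule that ramps the strength back to zero restores
    the pre-conditioning truth exactly.
    """
    plan = config.day_plan()
    for animal, group in truth.group_of.items():
        if group != GROUP_CTA:
            continue
        base = truth.gains[animal]["pretest1"]
        best = truth.best[animal]["pretest1"]
        rng = substream(config.seed, group, animal, "retune")
        full, affected = retune_gains(
            base, best, config.cta_retune_fraction, config.magnitude_preserving, rng
        )
        truth.retuned_cells.setdefault(animal, {})["cells"] = affected
        for day, kind in plan:
            s = config.retune_strength(day)
            if s <= 0 or kind in ("pretest", "conditioning"):
                continue
            mixed = base * (1.0 - s) + full * s
            truth.gains[animal][day] = mixed
            truth.best[animal][day] = best_labels(mixed)
    return truth
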