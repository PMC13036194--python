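"""Generator configuration and ground-truth containers."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from ..labels import (
    AVERSIVE_LABEL,
    BASIC_TASTES,
    CONDITIONING_LABEL,
    CS_LABEL,
    FORCED_CS_LABEL,
    GROUP_CONTROL,
    GROUP_CTA,
    WATER,
)

DEFAULT_PANEL = ("sucrose", "NaCl", "citric_acid", "QHCl_high", "QHCl_low", "KCl")

DEFAULT_CONCENTRATIONS = {
    "sucrose": "0.5 M",
    "NaCl": "0.3 M",
    "citric_acid": "0.02 M",
    "QHCl_high": "0.01 M",
    "QHCl_low": "0.03 mM",
    "KCl": "0.3 M",
}

# Mean licks per 5-s trial.  Appetitive stimuli cluster near the ceiling of
# the rhythmic lick rate; the high quinine concentration is strongly avoided.
DEFAULT_PALATABILITY = {
    "sucrose": 25.0,
    "NaCl": 22.0,
    "citric_acid": 18.0,
    "QHCl_high": 5.0,
    "QHCl_low": 24.0,
    "KCl": 20.0,
    WATER: 20.0,
}

# Latent identity coordinate per stimulus.  Cells preferring one stimulus
# spill over onto stimuli with nearby coordinates, giving the population an
# identity structure that is distinct from the palatability axis.
DEFAULT_IDENTITY_AXES = {
    "sucrose": 0.0,
    "NaCl": 1.0,
    "KCl": 1.3,
    "citric_acid": 2.2,
    "QHCl_low": 2.9,
    "QHCl_high": 3.2,
    WATER: 0.5,
}

@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-cohort generator.

    Defaults are tuned so that the generated cohorts express strong
    palatability coding (population dimension 1 tracks lick behavior),
    sparse identity tuning, and a conditioned-aversion effect implemented
    purely as cell-level re-tuning that preserves pooled response
    magnitudes.
    """

    n_animals_per_group: int = 3
    n_cells_per_animal: int = 40
    frame_rate: float = 10.0

    stimulus_panel: tuple[str, ...] = DEFAULT_PANEL
    concentrations: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CONCENTRATIONS))
    palatability_scores: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PALATABILITY))
    identity_axes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IDENTITY_AXES))

    # Trial structure
    trial_s: float = 5.0
    iti_s: float = 60.0
    n_blocks: int = 2
    session_start_s: float = 10.0

    # Cell tuning model
    cell_tuning_sparsity: float = 0.6
    response_gain_mean: float = 2.0
    response_gain_sd: float = 1.0
    baseline_gain: float = 0.15
    palatability_gain: float = 5.0
    aversive_cell_fraction: float = 0.5
    identity_sigma: float = 0.5

    # Calcium transient model
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.5
    noise_sd: float = 0.40
    event_rate_per_gain: float = 8.0
    event_amplitude: float = 0.125

    # Lick behavior
    lick_rate_hz: float = 8.0
    lick_dispersion: float = 50.0
    conditioning_lick_hz: float = 6.0
    conditioning_budget_mean: dict[str, float] = field(
        default_factory=lambda: {GROUP_CONTROL: 2000.0, GROUP_CTA: 900.0})
    conditioning_budget_dispersion: float = 8.0
    conditioning_cap_licks: int = 1000
    conditioning_cap_s: float = 1200.0

    # CTA effect
    cta_retune_fraction: float = 0.5
    magnitude_preserving: bool = True
    cta_lick_factor: float = 0.2
    #: Re-tuning strength applied on each post-conditioning day, in order.
    #: ``None`` means full strength (1.0) on every post day.
    retune_schedule: tuple[float, ...] | None = None

    #: Number of extinction sessions appended after the first post-test.
    extinction_days: int = 0

    groups: tuple[str, ...] = (GROUP_CONTROL, GROUP_CTA)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cell_tuning_sparsity", "cta_retune_fraction", "cta_lick_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if CS_LABEL not in self.stimulus_panel:
            raise ValueError(f"stimulus panel must contain the CS ({CS_LABEL!r})")
        if AVERSIVE_LABEL not in self.stimulus_panel:
            raise ValueError(f"stimulus panel must contain {AVERSIVE_LABEL!r}")
        if any(v < 0 for v in self.palatability_scores.values()):
            raise ValueError("palatability scores must be nonnegative")
        missing = [s for s in (*self.stimulus_panel, WATER)
                   if s not in self.palatability_scores]
        if missing:
            raise ValueError(f"palatability score missing for {missing}")

    # -- derived layout -------------------------------------------------

    @property
    def all_stimuli(self) -> tuple[str, ...]:
        return (*self.stimulus_panel, WATER)

    def day_plan(self) -> list[tuple[str, str]]:
        """Ordered ``(day_name, day_kind)`` pairs for one cohort."""
        plan = [
            ("pretest1", "pretest"),
            ("pretest2", "pretest"),
            ("conditioning", "conditioning"),
            ("posttest1", "posttest"),
        ]
        for i in range(self.extinction_days):
            plan.append((f"posttest{i + 2}", "extinction"))
        return plan

    def retune_strength(self, day_name: str) -> float:
        """Re-tuning strength in [0, 1] applied on a given day (CTA group)."""
        post_days = [d for d, k in self.day_plan() if k in ("posttest", "extinction")]
        if day_name not in post_days:
            return 0.0
        if self.retune_schedule is None:
            return 1.0
        idx = post_days.index(day_name)
        if idx >= len(self.retune_schedule):
            return float(self.retune_schedule[-1])
        return float(self.retune_schedule[idx])

    @classmethod
    def extinction_defaults(cls, **kwargs: Any) -> "GeneratorConfig":
        """Config for an extinction cohort: three extra post days over which
        the re-tuning (and the lick suppression) ramps back down to zero."""
        kwargs.setdefault("extinction_days", 3)
        kwargs.setdefault("retune_schedule", (1.0, 1.0, 0.5, 0.0))
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class GroundTruth:
    """Generator-side truth recorded for verification.

    ``gains`` maps animal -> day -> DataFrame (cells x stimuli, columns
    include water); ``best`` maps animal -> day -> Series of basic-taste
    best-stimulus labels; ``lick_counts`` maps (animal, day) -> DataFrame
    with per-trial counts.  Cell indices are stable across days and double
    as the registration ground truth.
    """

    group_of: dict[str, str] = field(default_factory=dict)
    gains: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)
    best: dict[str, dict[str, pd.Series]] = field(default_factory=dict)
    retuned_cells: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    lick_counts: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def pooled_positive_cs_gain(self, day: str, group: str | None = None) -> float:
        """Mean of positive CS gains pooled over all cells (optionally one group)."""
        vals: list[np.ndarray] = []
        for animal, per_day in self.gains.items():
            if group is not None and self.group_of[animal] != group:
                continue
            g = per_day[day][CS_LABEL].to_numpy()
            vals.append(g[g > 0])
        pooled = np.concatenate(vals) if vals else np.array([])
        return float(pooled.mean()) if pooled.size else float("nan")
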