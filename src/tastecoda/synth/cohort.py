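"""Cohort-level generation and on-disk format.

A cohort is a control group plus a conditioned group, each with several
animals recorded over the full session sequence (two pretest days, one
conditioning day, one or more post-test days).  On disk a cohort is a
directory of plain CSV files plus a JSON manifest and a ground-truth
file; in memory it is a list of :class:`~tastecoda.extraction.SessionData`
plus a :class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .._rng import substream
from ..extraction import SessionData
from ..labels import GROUP_CTA
from .config import GeneratorConfig, GroundTruth
from .licks import simulate_licks
from .retune import apply_cta_retuning
from .schedule import build_schedule
from .traces import best_labels, draw_base_gains, synthesize_traces

__all__ = ["Cohort", "generate_cohort", "write_cohort", "load_ground_truth"]


@dataclass
class Cohort:
    config: GeneratorConfig
    sessions: list[SessionData] = field(default_factory=list)
    truth: GroundTruth = field(default_factory=GroundTruth)

    def animals(self, group: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sessions:
            if group is None or s.group == group:
                seen.setdefault(s.animal_id, None)
        return list(seen)

    def session(self, animal: str, day: str) -> SessionData:
        for s in self.sessions:
            if s.animal_id == animal and s.day == day:
                return s
        raise KeyError(f"no session for animal {animal!r} on day {day!r}")

    def manifest(self) -> dict:
        groups: dict[str, list[str]] = {}
        for s in self.sessions:
            groups.setdefault(s.group, [])
            if s.animal_id not in groups[s.group]:
                groups[s.group].append(s.animal_id)
        return {
            "groups": groups,
            "days": [{"name": d, "kind": k} for d, k in self.config.day_plan()],
            "frame_rate": self.config.frame_rate,
            "stimulus_panel": list(self.config.stimulus_panel),
            "concentrations": self.config.concentrations,
            "seed": self.config.seed,
            "config": self.config.to_dict(),
        }


def generate_cohort(
    config: GeneratorConfig,
    groups: tuple[str, ...] | None = None,
    with_traces: bool = True,
) -> Cohort:
    """Generate a full synthetic cohort.

    ``groups`` restricts generation to a subset of ``config.groups``;
    restriction never changes what the remaining groups contain, because
    every random stream is keyed by (seed, group, animal, day, purpose).
    ``with_traces=False`` produces schedule/lick-only sessions (empty
    trace matrices) for behavior-only analyses.
    """
    groups = tuple(groups) if groups is not None else config.groups
    plan = config.day_plan()
    truth = GroundTruth()

    # Tuning ground truth first (base gains on every day, then re-tuning)
    for group in groups:
        for i in range(config.n_animals_per_group):
            animal = f"{group}{i + 1:02d}"
            truth.group_of[animal] = group
            base = draw_base_gains(config, substream(config.seed, group, animal, "gains"))
            best = best_labels(base)
            truth.gains[animal] = {day: base for day, _ in plan}
            truth.best[animal] = {day: best for day, _ in plan}
    apply_cta_retuning(truth, config)

    cohort = Cohort(config=config, truth=truth)
    cell_ids = np.arange(config.n_cells_per_animal)
    for animal, group in truth.group_of.items():
        for day, kind in plan:
            strength = config.retune_strength(day) if group == GROUP_CTA else 0.0
            trials = build_schedule(kind, config, substream(config.seed, group, animal, day, "sched"))
            licks = simulate_licks(
                trials, config, group, kind,
                substream(config.seed, group, animal, day, "licks"),
                retune_strength=strength,
            )
            counts = (licks.groupby("trial_id").size()
                      .reindex(trials["trial_id"], fill_value=0))
            truth.lick_counts[(animal, day)] = pd.DataFrame(
                {"trial_id": trials["trial_id"], "count": counts.to_numpy()})
            if with_traces:
                traces = synthesize_traces(
                    trials, licks, truth.gains[animal][day], config,
                    substream(config.seed, group, animal, day, "traces"),
                    day_kind=kind,
                )
            else:
                traces = np.zeros((config.n_cells_per_animal, 0))
            cohort.sessions.append(SessionData(
                animal_id=animal, day=day, day_kind=kind, group=group,
                traces=traces, frame_rate=config.frame_rate,
                trials=trials, licks=licks, global_cell_ids=cell_ids.copy(),
            ))
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort directory (manifest, ground truth, per-session CSVs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "manifest.json").write_text(
        json.dumps(cohort.manifest(), indent=1, sort_keys=True))

    truth = cohort.truth
    gt = {
        "stimulus_order": list(cohort.config.all_stimuli),
        "group_of": truth.group_of,
        "gains": {a: {d: {s: [round(float(v), 6) for v in df[s]] for s in df.columns}
                      for d, df in per_day.items()}
                  for a, per_day in truth.gains.items()},
        "best": {a: {d: list(b) for d, b in per_day.items()}
                 for a, per_day in truth.best.items()},
        "retuned_cells": truth.retuned_cells,
    }
    (path / "ground_truth.json").write_text(json.dumps(gt, sort_keys=True))

    for s in cohort.sessions:
        day_dir = path / s.animal_id / s.day
        day_dir.mkdir(parents=True, exist_ok=True)
        traces = pd.DataFrame(
            s.traces, index=pd.Index(s.global_cell_ids, name="cell"))
        traces.columns = [f"f{j}" for j in range(traces.shape[1])]
        traces.to_csv(day_dir / "traces.csv", float_format="%.5f")
        s.trials.to_csv(day_dir / "trials.csv", index=False)
        s.licks.to_csv(day_dir / "licks.csv", index=False, float_format="%.4f")
    return path


def load_ground_truth(path: str | Path) -> GroundTruth:
    raw = json.loads((Path(path) / "ground_truth.json").read_text())
    truth = GroundTruth(group_of=raw["group_of"], retuned_cells=raw["retuned_cells"])
    order = raw.get("stimulus_order")
    for a, per_day in raw["gains"].items():
        truth.gains[a] = {d: pd.DataFrame(cols)[order or sorted(cols)]
                          for d, cols in per_day.items()}
        truth.best[a] = {d: pd.Series(v) for d, v in raw["best"][a].items()}
    return truth
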