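"""Cell-tuning model and fluorescence-trace synthesis.

Each cell's response gain to a stimulus is the sum of three parts: a small
nonspecific baseline, a sparse identity component (a preferred stimulus
plus spillover to stimuli with nearby latent identity coordinates), and a
palatability component proportional to the stimulus's normalized lick
score.  Traces are a constant baseline plus Gaussian noise plus
difference-of-exponential transients triggered by a Poisson event train
whose rate during the trial's lick window scales with the cell's gain for
that trial's stimulus.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import (
    BASIC_TASTES,
    CONDITIONING_LABEL,
    FORCED_CS_LABEL,
    WATER,
    GeneratorConfig,
)

__all__ = ["draw_base_gains", "best_labels", "transient_kernel", "synthesize_traces"]


def draw_base_gains(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one animal's gain matrix (cells x stimuli, water included)."""
    stimuli = config.all_stimuli
    n, m = config.n_cells_per_animal, len(stimuli)
    axes = np.array([config.identity_axes[s] for s in stimuli])
    score_max = max(config.palatability_scores.values()) or 1.0
    palat = np.array([config.palatability_scores[s] / score_max for s in stimuli])

    gains = np.abs(rng.normal(config.baseline_gain, config.baseline_gain / 2, (n, m)))
    # Palatability component: appetitive-preferring cells load on the
    # normalized lick score, aversive-preferring cells on its complement.
    # The two sub-populations make palatability a population *pattern*, so
    # moving one stimulus along the palatability axis re-tunes cells
    # without changing the pooled response magnitude.
    w = config.palatability_gain * rng.uniform(0.5, 1.5, size=n)
    aversive_type = rng.random(n) < config.aversive_cell_fraction
    curve = np.where(aversive_type[:, None], 1.0 - palat[None, :], palat[None, :])
    gains += w[:, None] * curve
    # Sparse identity component with Gaussian spillover along the axis
    tuned = rng.random(n) < config.cell_tuning_sparsity
    pref = rng.integers(0, len(config.stimulus_panel), size=n)
    boost = np.abs(rng.normal(config.response_gain_mean, config.response_gain_sd, n))
    for c in np.flatnonzero(tuned):
        d = axes - axes[pref[c]]
        gains[c] += boost[c] * np.exp(-(d ** 2) / (2 * config.identity_sigma ** 2))
    return pd.DataFrame(gains, columns=list(stimuli))


def best_labels(gains: pd.DataFrame) -> pd.Series:
    """Best basic-taste label per cell (ties broken by fixed panel order)."""
    basic = gains[list(BASIC_TASTES)]
    return basic.idxmax(axis=1)


def transient_kernel(config: GeneratorConfig) -> np.ndarray:
    """Unit-peak difference-of-exponentials calcium kernel, sampled at the
    configured frame rate."""
    t = np.arange(0.0, config.kernel_decay_s * 6, 1.0 / config.frame_rate)
    k = np.exp(-t / config.kernel_decay_s) - np.exp(-t / config.kernel_rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("kernel rise must be faster than decay")
    return k / peak


def _first_lick(licks: pd.DataFrame, trial_id: int, onset: float, trial_s: float) -> float | None:
    t = licks.loc[licks["trial_id"] == trial_id, "lick_time_s"].to_numpy()
    t = t[(t >= onset) & (t < onset + trial_s)]
    return float(t.min()) if t.size else None


def synthesize_traces(
    trials: pd.DataFrame,
    licks: pd.DataFrame,
    gains: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
    day_kind: str = "pretest",
) -> np.ndarray:
    """Synthesize one session's trace matrix (cells x frames)."""
    fr = config.frame_rate
    n_cells = len(gains)
    if day_kind == "conditioning":
        end = max(60.0, licks["lick_time_s"].max() if len(licks) else 0.0) + 10.0
        n_frames = int(math.ceil(end * fr))
        return 1.0 + rng.normal(0.0, config.noise_sd, (n_cells, n_frames))

    end = trials["onset_s"].max() + config.trial_s + 10.0
    n_frames = int(math.ceil(end * fr))
    traces = 1.0 + rng.normal(0.0, config.noise_sd, (n_cells, n_frames))
    kernel = transient_kernel(config)

    # Event trains accumulate as per-frame impulses, then one convolution
    # with the transient kernel per cell.
    impulses = np.zeros((n_cells, n_frames))
    for trial in trials.itertuples():
        stim = trial.stimulus
        if stim == FORCED_CS_LABEL:
            stim = "NaCl"
        if stim == CONDITIONING_LABEL:
            continue
        if stim not in gains.columns:
            raise KeyError(f"no gain column for stimulus {stim!r}")
        start = _first_lick(licks, trial.trial_id, trial.onset_s, config.trial_s)
        if start is None:
            start = float(trial.onset_s)
        rates = config.event_rate_per_gain * gains[stim].to_numpy()
        counts = rng.poisson(np.clip(rates, 0, None) * config.trial_s)
        for c in np.flatnonzero(counts):
            times = rng.uniform(start, start + config.trial_s, counts[c])
            amps = config.event_amplitude * rng.uniform(0.75, 1.25, counts[c])
            frames = (times * fr).astype(int)
            keep = frames < n_frames
            np.add.at(impulses[c], frames[keep], amps[keep])
    for c in range(n_cells):
        if impulses[c].any():
            traces[c] += np.convolve(impulses[c], kernel)[:n_frames]
    return traces
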