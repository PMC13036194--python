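# tastecoda

Analysis pipeline for taste-evoked calcium-imaging responses recorded across
conditioning days in freely licking animals, together with a synthetic-cohort
generator that emulates the full experiment (trial schedules, lickometer
behavior, GCaMP-like traces, and a learned-aversion effect implemented as
cell-level re-tuning) so every stage can be exercised and validated against
known ground truth.

## Stages

| Module | What it does |
| --- | --- |
| `tastecoda.synth` | Generates cohorts: taste-panel schedules (12 stimulus + 12 water trials in 2 pseudorandom blocks), conditioning sessions capped at 1,000 licks or 20 min, extinction sessions opening with 12 forced CS trials, negative-binomial lick behavior, and traces built from Poisson event trains convolved with a difference-of-exponentials kernel. The conditioned-aversion effect re-tunes a configurable fraction of quinine-best cells (gain CS sensitivity) and CS-best cells (lose it) while conserving pooled response magnitude exactly. |
| `tastecoda.extraction` | Trial-aligned responses: 5-s response window from the first lick (onset fallback for zero-lick trials), baseline the 5 s before it, `delta_plus/delta_minus` per cell × trial, excited/suppressed calls at the inclusive ±3·SD criterion, day-averaged tables, and restriction to cells tracked on all days. |
| `tastecoda.tuning` | Breadth-of-tuning entropy (H = −K Σ pᵢ log₁₀ pᵢ, K = 1/log₁₀ 4 over the four basic tastes), best-stimulus unit labels from the second pretest day, and the post-conditioning tuning-shift table for N-Units and Q-Units. |
| `tastecoda.geometry` | Pooled population vectors per stimulus × day, joint principal-coordinates embedding with scree-rule dimensionality, Euclidean-distance readouts (CS divergence from accepted stimuli, extinction trajectories), dimension-1 orientation against lick behavior, and Lance–Williams complete-linkage clustering. |
| `tastecoda.decoding` | Linear-SVM decoding: leave-one-out protocols for stimulus identity and binary palatability (with shuffled-label and bootstrap distributions) and the train-pre/test-post protocol with row-normalized confusion matrices. |
| `tastecoda.behavior` | Lickometer analytics: per-stimulus lick summaries with forced/unforced splits, conditioning metrics (first-minute licks, licks/min, minutes to the 1,000-lick cap), paired comparisons, and the per-trial response-vs-licks regression. |
| `tastecoda.pipeline` / `tastecoda.cli` | End-to-end orchestration with full seed determinism and a JSON report. |

## CLI

```bash
tastecoda generate --out cohort/ --seed 1            # write a synthetic cohort
tastecoda extract  --cohort cohort/ --out results/   # response tables
tastecoda tune     --cohort cohort/ --out results/
tastecoda geometry --cohort cohort/ --out results/
tastecoda decode   --cohort cohort/ --out results/ --protocol pre2post
tastecoda behavior --cohort cohort/ --out results/
tastecoda run-all  --out results/ --seed 1           # everything, one report
```

Generator settings can be supplied as YAML via `--config` (keys matching
`GeneratorConfig` fields). A cohort directory contains, per animal and day,
`traces.csv` (cells × frames), `trials.csv` (trial_id, stimulus, onset_s,
block, forced), `licks.csv` (trial_id, lick_time_s), plus `manifest.json` and
`ground_truth.json`.

## Determinism

One global seed expands into substreams keyed by (group, animal, day,
purpose), so adding animals or restricting generation to one group never
changes the data of existing animals, and `run-all` reports are
byte-identical across reruns with the same seed.
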