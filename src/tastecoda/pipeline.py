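"""End-to-end orchestration: generate/load -> extract -> tune -> geometry
-> decode -> behavior -> report.

Every stage's tabular output is written as CSV next to a single JSON
report; the report carries the effective configuration, its hash, and the
seed, and is byte-identical across reruns with the same seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import decoding as dec
from . import geometry as geo
from . import tuning as tun
from .extraction import ResponseTable, build_response_table, filter_tracked, summarize_responses
from .labels import BASIC_TASTES, CS_LABEL, GROUP_CTA, WATER
from .synth import Cohort, GeneratorConfig, generate_cohort
from .tuning import DEFAULT_REFERENCE_DAY

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "analyze_cohort", "jsonify"]


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    out_dir: str | Path | None = None
    do_tuning: bool = True
    do_geometry: bool = True
    do_decoding: bool = True
    do_behavior: bool = True
    decode_shuffles: int = 50
    decode_bootstraps: int = 50
    reference_day: str = DEFAULT_REFERENCE_DAY
    post_day: str = "posttest1"


def jsonify(obj: Any) -> Any:
    """Recursively convert pandas/numpy containers to JSON-native types."""
    if isinstance(obj, dict):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return jsonify(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return jsonify(obj.to_dict())
    if isinstance(obj, np.ndarray):
        return jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _config_hash(config: GeneratorConfig) -> str:
    blob = json.dumps(jsonify(config.to_dict()), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def session_lick_counts(cohort: Cohort) -> pd.DataFrame:
    """Per-trial lick counts over all non-conditioning sessions."""
    rows = []
    for s in cohort.sessions:
        if s.day_kind == "conditioning":
            continue
        counted = bhv.count_licks_per_trial(s.licks, s.trials)
        counted.insert(0, "animal", s.animal_id)
        counted.insert(1, "group", s.group)
        counted.insert(2, "day", s.day)
        rows.append(counted)
    return pd.concat(rows, ignore_index=True)


def group_lick_means(lick_counts: pd.DataFrame, day: str,
                     group: str | None = None) -> dict[str, float]:
    """Cross-animal mean lick count per stimulus on one day."""
    sub = lick_counts[lick_counts["day"] == day]
    if group is not None:
        sub = sub[sub["group"] == group]
    return sub.groupby("stimulus")["count"].mean().to_dict()


def geometry_section(
    table: ResponseTable,
    lick_counts: pd.DataFrame,
    group: str,
    post_day: str,
    pre_day: str = DEFAULT_REFERENCE_DAY,
) -> dict:
    """Embedding, CS-divergence series, and the dimension-1/behavior fit
    for one group."""
    vectors = geo.build_population_vectors(table.averaged, group)
    emb = geo.embed_population(vectors, d="scree")
    days = [d for d in table.averaged["day"].unique()]
    series_days = [d for d in days if d == pre_day or d.startswith("posttest")]
    divergence = geo.cs_divergence(emb, series_days)
    licks = group_lick_means(lick_counts, post_day, group)
    dim1, fit = geo.orient_and_correlate(emb, licks, post_day)
    return {
        "group": group,
        "objects": emb.objects,
        "coordinates": emb.coordinates[:, :emb.d],
        "eigenvalues": emb.eigenvalues,
        "d": emb.d,
        "cs_divergence": divergence,
        "dim1_post": {f"{s}|{d}": v for (s, d), v in dim1.items()},
        "dim1_lick_fit": fit,
    }


def decoding_section(table: ResponseTable, lick_counts: pd.DataFrame,
                     group: str, config: RunConfig,
                     pre_days: list[str], seed: int) -> dict:
    """Both SVM protocols for one group."""
    out: dict[str, Any] = {"group": group}
    # LOOCV identity on day-averaged observations, all stimuli, all days
    X, y = dec.assemble_observations(table.averaged, group, mode="per_day_average")
    day_groups = np.array([idx[0] for idx in X.index])
    res = dec.loocv_svm(X, y, shuffles=config.decode_shuffles,
                        bootstraps=config.decode_bootstraps, seed=seed,
                        day_groups=day_groups)
    out["loocv_identity"] = _decoding_dict(res)

    # LOOCV binary palatability: label each (day, stimulus) row by the day's
    # lick-count split
    y_pal = []
    for day, stim in X.index:
        labels, _ = dec.label_palatability(lick_counts[lick_counts["group"] == group], day)
        y_pal.append(labels[stim])
    try:
        res_pal = dec.loocv_svm(X, pd.Series(y_pal, index=X.index),
                                shuffles=config.decode_shuffles,
                                bootstraps=config.decode_bootstraps,
                                seed=seed + 1, day_groups=day_groups)
        out["loocv_palatability"] = _decoding_dict(res_pal)
    except ValueError as err:
        out["loocv_palatability"] = {"error": str(err)}

    # Train-pre / test-post, basic tastes, trial mode
    post_days = sorted({d for d in table.trials["day"].unique()
                        if d.startswith("posttest")})
    Xpre, ypre = dec.assemble_observations(
        table.trials, group, mode="per_trial",
        stimulus_set=BASIC_TASTES, days=pre_days)
    Xpost, ypost = dec.assemble_observations(
        table.trials, group, mode="per_trial",
        stimulus_set=BASIC_TASTES, days=post_days[:1])
    res_p2p = dec.pre2post_svm(Xpre, ypre, Xpost, ypost,
                               bootstraps=config.decode_bootstraps, seed=seed + 2)
    out["pre2post"] = _decoding_dict(res_p2p)
    return out


def _decoding_dict(res: dec.DecodingResult) -> dict:
    return {
        "accuracy": res.accuracy,
        "error_rate": res.error_rate,
        "class_labels": res.class_labels,
        "shuffled_mean": float(np.nanmean(res.shuffled)) if res.shuffled.size else None,
        "shuffled": res.shuffled,
        "bootstrap_mean": float(np.nanmean(res.bootstrap)) if res.bootstrap.size else None,
        "confusion_counts": res.confusion_counts,
        "confusion_percent": res.confusion_percent,
    }


def behavior_section(cohort: Cohort, table: ResponseTable,
                     lick_counts: pd.DataFrame, post_day: str) -> dict:
    """Lick summaries, conditioning metrics, CS pre/post comparison, and
    the per-trial response-vs-licks regression per group."""
    sess = [(s.animal_id, s.group, s.day, s.trials, s.licks)
            for s in cohort.sessions if s.day_kind != "conditioning"]
    summary = bhv.lick_summary(sess)
    conditioning = []
    for s in cohort.sessions:
        if s.day_kind != "conditioning":
            continue
        m = bhv.conditioning_metrics(s.licks)
        m.update({"animal": s.animal_id, "group": s.group})
        conditioning.append(m)

    groups = sorted({s.group for s in cohort.sessions})
    regressions = {}
    cs_tests = {}
    for g in groups:
        fit, _ = bhv.response_vs_licks(
            table.trials[table.trials["group"] == g],
            lick_counts[lick_counts["group"] == g])
        regressions[g] = fit
        cs = summary[(summary["group"] == g) & (summary["stimulus"] == CS_LABEL)]
        pre = cs[cs["day"] == DEFAULT_REFERENCE_DAY].set_index("animal")["mean_licks"]
        post = cs[cs["day"] == post_day].set_index("animal")["mean_licks"]
        common = pre.index.intersection(post.index)
        if len(common) >= 2:
            cs_tests[g] = bhv.paired_comparison(pre[common].to_numpy(),
                                                post[common].to_numpy())
    return {
        "lick_summary": summary,
        "conditioning": conditioning,
        "response_vs_licks": regressions,
        "cs_pre_post": cs_tests,
    }


def analyze_cohort(cohort: Cohort, config: RunConfig | None = None) -> dict:
    """Run every enabled analysis stage on an in-memory cohort."""
    config = config or RunConfig(generator=cohort.config)
    seed = cohort.config.seed
    report: dict[str, Any] = {
        "manifest": {
            "seed": seed,
            "config_hash": _config_hash(cohort.config),
            "config": cohort.config.to_dict(),
        },
    }
    imaging = [s for s in cohort.sessions if s.day_kind != "conditioning"]
    tracked, tracked_report = filter_tracked(imaging)
    report["tracked_cells"] = tracked_report
    table = build_response_table(tracked)
    report["responses"] = {
        "summary": summarize_responses(table),
        "n_dropped_trials": len(table.dropped_trials),
        "n_dual_threshold": table.n_both_flagged,
    }
    lick_counts = session_lick_counts(cohort)
    groups = sorted({s.group for s in cohort.sessions})
    pre_days = sorted({d for d in table.averaged["day"].unique()
                       if d.startswith("pretest")})

    if config.do_tuning:
        labels = tun.assign_best_stimulus(table.averaged, config.reference_day)
        shift, _ = tun.tuning_shift_table(labels, table.averaged, config.post_day)
        ttab = tun.tuning_table(table.averaged)
        entropy_means = (ttab.dropna(subset=["entropy"])
                         .merge(table.averaged[["animal", "group"]].drop_duplicates(),
                                on="animal")
                         .groupby(["group", "day"])["entropy"].mean().reset_index())
        report["tuning"] = {"unit_labels": labels, "shift_table": shift,
                            "entropy_means": entropy_means}
    if config.do_geometry:
        report["geometry"] = {
            g: geometry_section(table, lick_counts, g, config.post_day)
            for g in groups}
    if config.do_decoding:
        report["decoding"] = {
            g: decoding_section(table, lick_counts, g, config, pre_days, seed)
            for g in groups}
    if config.do_behavior:
        report["behavior"] = behavior_section(cohort, table, lick_counts,
                                              config.post_day)
    report["_tables"] = {"response_table": table, "lick_counts": lick_counts}
    return report


def run_all(config: RunConfig) -> dict:
    """Generate the synthetic cohort and run the full pipeline; write the
    report bundle when ``out_dir`` is set."""
    cohort = generate_cohort(config.generator)
    report = analyze_cohort(cohort, config)
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = report.pop("_tables", {})
    if "response_table" in tables:
        tables["response_table"].trials.to_csv(out / "responses_trials.csv",
                                               index=False, float_format="%.6g")
        tables["response_table"].averaged.to_csv(out / "responses_averaged.csv",
                                                 index=False, float_format="%.6g")
    if "lick_counts" in tables:
        tables["lick_counts"].to_csv(out / "lick_counts.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(jsonify(report), indent=1, sort_keys=True))
    return out / "report.json"
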