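"""Population decoding with support-vector classifiers.

Two protocols: leave-one-out cross-validation on the full observation set
(stimulus identity or binary palatability labels), with shuffled-label
and bootstrap distributions; and the train-pre/test-post protocol in
which one model is fitted on all pre-conditioning observations and
evaluated on post-conditioning ones via a confusion matrix.

The classifier is a linear-kernel SVM with features standardized inside
each training fold and the regularization strength chosen from a small
grid by inner cross-validation (one-vs-one for multiclass problems).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (0.1, 1.0, 10.0)


@dataclass
class DecodingResult:
    protocol: str
    class_labels: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    accuracy: float
    shuffled: np.ndarray = field(default_factory=lambda: np.empty(0))
    bootstrap: np.ndarray = field(default_factory=lambda: np.empty(0))
    confusion_counts: pd.DataFrame | None = None
    confusion_percent: pd.DataFrame | None = None

    @property
    def error_rate(self) -> float:
        return 1.0 - self.accuracy


def assemble_observations(
    table: pd.DataFrame,
    group: str,
    mode: str = "per_day_average",
    stimulus_set: tuple[str, ...] | None = None,
    days: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix plus identity labels for one group.

    ``table`` is the trial-level response table for ``per_trial`` mode or
    the day-averaged table for ``per_day_average``.  Rows are stimulus x
    day observations (x trial repetition in trial mode); columns are
    pooled tracked cells, one per (animal, cell).  Trial mode aligns each
    animal's k-th trial of a stimulus; repetitions present in only some
    animals are dropped with a log entry.
    """
    sub = table[table["group"] == group].copy()
    if days is not None:
        sub = sub[sub["day"].isin(days)]
    if stimulus_set is not None:
        missing = set(stimulus_set) - set(sub["stimulus"].unique())
        if missing:
            raise ValueError(f"requested stimuli absent: {sorted(missing)}")
        sub = sub[sub["stimulus"].isin(stimulus_set)]
    if sub.empty:
        raise ValueError(f"no observations for group {group!r}")

    if mode == "per_day_average":
        X = sub.pivot_table(index=["day", "stimulus"],
                            columns=["animal", "cell"], values="delta_plus")
    elif mode == "per_trial":
        sub["rep"] = (sub.groupby(["animal", "day", "stimulus", "cell"])
                      .cumcount())
        X = sub.pivot_table(index=["day", "stimulus", "rep"],
                            columns=["animal", "cell"], values="delta_plus")
        n_before = len(X)
        X = X.dropna(how="any")
        if len(X) < n_before:
            logger.info("dropped %d trial rows with unmatched repetition counts",
                        n_before - len(X))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if X.isna().any().any():
        raise ValueError("missing cell values in assembled observations")
    labels = pd.Series([idx[1] for idx in X.index], index=X.index, name="stimulus")
    return X, labels


def label_palatability(
    lick_counts: pd.DataFrame, day: str
) -> tuple[dict[str, str], int]:
    """Binary palatability label per stimulus on one day.

    ``lick_counts`` needs columns ``day, stimulus, count`` (one row per
    trial, all animals).  A stimulus is ``high`` when its cross-animal
    mean lick count exceeds the median lick count over all of that day's
    trials; ties label ``low``.  Returns the label map and the tie count.
    """
    sub = lick_counts[lick_counts["day"] == day]
    if sub.empty:
        raise ValueError(f"no lick counts for day {day!r}")
    median = sub["count"].median()
    means = sub.groupby("stimulus")["count"].mean()
    labels = {s: ("high" if m > median else "low") for s, m in means.items()}
    ties = int((means == median).sum())
    if ties:
        logger.info("%d stimuli tied with the day median; labeled low", ties)
    return labels, ties


def _fit_and_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    c_grid: tuple[float, ...],
    seed: int = 0,
) -> np.ndarray:
    base = make_pipeline(StandardScaler(),
                         SVC(kernel="linear", C=c_grid[0], random_state=seed))
    _, counts = np.unique(y_train, return_counts=True)
    n_splits = min(3, counts.min())
    if len(c_grid) > 1 and n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits)
        model = GridSearchCV(base, {"svc__C": list(c_grid)}, cv=cv, n_jobs=None)
    else:
        model = base
    model.fit(X_train, y_train)
    return model.predict(X_test)


def _loocv_predict(
    X: np.ndarray, y: np.ndarray, c_grid: tuple[float, ...]
) -> np.ndarray:
    n = len(y)
    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        preds[i] = _fit_and_predict(X[mask], y[mask], X[i:i + 1], c_grid)[0]
    return preds.astype(str)


def _permute_within(rng: np.random.Generator, y: np.ndarray,
                    groups: np.ndarray | None) -> np.ndarray:
    out = np.array(y, copy=True)
    if groups is None:
        return rng.permutation(out)
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        out[idx] = out[idx[rng.permutation(len(idx))]]
    return out


def _confusion(y_true: np.ndarray, y_pred: np.ndarray,
               class_labels: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    cm = confusion_matrix(y_true, y_pred, labels=class_labels)
    counts = pd.DataFrame(cm, index=class_labels, columns=class_labels)
    row_sums = counts.sum(axis=1).replace(0, np.nan)
    percent = counts.div(row_sums, axis=0) * 100.0
    return counts, percent


def loocv_svm(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    shuffles: int = 1000,
    bootstraps: int = 1000,
    seed: int = 0,
    day_groups: np.ndarray | None = None,
    c_grid: tuple[float, ...] = (1.0,),
) -> DecodingResult:
    """Leave-one-out SVM decoding with shuffled-label and bootstrap
    distributions.

    Shuffle repetitions permute the labels (within ``day_groups`` when
    given, preserving day structure) and rerun the full LOOCV; bootstrap
    repetitions resample observations with replacement and rerun LOOCV on
    the resample.  A fixed ``seed`` reproduces both distributions
    exactly.  ``c_grid`` defaults to a single fixed regularization
    strength because LOOCV is repeated for every shuffle/bootstrap; pass
    ``DEFAULT_C_GRID`` to select C by inner cross-validation instead.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y).astype(str)
    classes, counts = np.unique(ya, return_counts=True)
    if len(classes) < 2 or len(ya) < 3:
        raise ValueError("need at least 2 classes and 3 observations")
    if counts.min() < 2:
        logger.warning("classes with a single observation have degenerate "
                       "LOOCV folds: %s", classes[counts < 2].tolist())
    rng = np.random.default_rng(seed)

    preds = _loocv_predict(Xa, ya, c_grid)
    accuracy = float(np.mean(preds == ya))

    shuffled = np.empty(shuffles)
    for r in range(shuffles):
        y_sh = _permute_within(rng, ya, day_groups)
        shuffled[r] = np.mean(_loocv_predict(Xa, y_sh, c_grid) == y_sh)

    bootstrap = np.empty(bootstraps)
    for r in range(bootstraps):
        idx = rng.integers(0, len(ya), len(ya))
        if len(np.unique(ya[idx])) < 2:
            bootstrap[r] = np.nan
            continue
        bootstrap[r] = np.mean(_loocv_predict(Xa[idx], ya[idx], c_grid) == ya[idx])

    cm_counts, cm_pct = _confusion(ya, preds, list(classes))
    return DecodingResult(
        protocol="loocv", class_labels=list(classes), y_true=ya, y_pred=preds,
        accuracy=accuracy, shuffled=shuffled, bootstrap=bootstrap,
        confusion_counts=cm_counts, confusion_percent=cm_pct,
    )


def pre2post_svm(
    X_pre: pd.DataFrame,
    y_pre: pd.Series | np.ndarray,
    X_post: pd.DataFrame,
    y_post: pd.Series | np.ndarray,
    bootstraps: int = 1000,
    seed: int = 0,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
) -> DecodingResult:
    """Train on pre-conditioning observations, test on post-conditioning.

    Feature columns (pooled cells) must match between the two sets.  The
    bootstrap resamples post observations with replacement and records
    the prediction accuracy of each resample.
    """
    if isinstance(X_pre, pd.DataFrame) and isinstance(X_post, pd.DataFrame):
        if list(X_pre.columns) != list(X_post.columns):
            raise ValueError("pre and post feature columns differ")
    Xa, Xb = np.asarray(X_pre, float), np.asarray(X_post, float)
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("pre and post feature dimensionality differ")
    ya, yb = np.asarray(y_pre).astype(str), np.asarray(y_post).astype(str)

    preds = _fit_and_predict(Xa, ya, Xb, c_grid).astype(str)
    accuracy = float(np.mean(preds == yb))
    rng = np.random.default_rng(seed)
    bootstrap = np.empty(bootstraps)
    for r in range(bootstraps):
        idx = rng.integers(0, len(yb), len(yb))
        bootstrap[r] = np.mean(preds[idx] == yb[idx])

    class_labels = sorted(set(ya) | set(yb))
    cm_counts, cm_pct = _confusion(yb, preds, class_labels)
    return DecodingResult(
        protocol="pre2post", class_labels=class_labels, y_true=yb, y_pred=preds,
        accuracy=accuracy, bootstrap=bootstrap,
        confusion_counts=cm_counts, confusion_percent=cm_pct,
    )
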