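"""Population-geometry analyses.

Stimulus x day population vectors (cells pooled across the animals of one
group) are embedded jointly by principal coordinates analysis (classical
MDS) so that trajectories across days share axes.  Distance readouts are
plain Euclidean distances in the embedding; dimensionality defaults to
the scree rule's elbow.  Agglomerative clustering is provided through the
Lance-Williams update with complete-linkage coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .labels import AVERSIVE_LABEL, CS_LABEL, WATER

DEFAULT_ACCEPTED = ("sucrose", "KCl", "citric_acid", "QHCl_low", WATER)


@dataclass
class EmbeddingResult:
    """Joint PCoA embedding of (stimulus, day) objects."""

    objects: list[tuple[str, str]]  # (stimulus, day)
    coordinates: np.ndarray  # objects x n_positive_eigenvalues
    eigenvalues: np.ndarray  # descending, negatives included
    d: int  # chosen dimensionality
    orientation: np.ndarray  # +/-1 sign applied per retained axis

    def coords(self, stimulus: str, day: str, d: int | None = None) -> np.ndarray:
        idx = self.objects.index((stimulus, day))
        return self.coordinates[idx, : (d or self.d)]

    def dimension(self, axis: int, day: str | None = None) -> pd.Series:
        """One embedding axis as a Series keyed by (stimulus, day)."""
        sel = [(i, o) for i, o in enumerate(self.objects)
               if day is None or o[1] == day]
        return pd.Series({o: self.coordinates[i, axis] for i, o in sel})


def build_population_vectors(
    averaged: pd.DataFrame,
    group: str,
    days: list[str] | None = None,
) -> pd.DataFrame:
    """Stimulus x day population-vector matrix for one group.

    Rows are (stimulus, day) pairs; columns are pooled tracked cells,
    keyed (animal, cell); values are the day-averaged response of that
    cell to that stimulus.  Raises if any pooled cell is missing a
    stimulus-day mean (cannot happen after tracked-cell filtering).
    """
    sub = averaged[averaged["group"] == group]
    if sub.empty:
        raise ValueError(f"no data for group {group!r}")
    if days is not None:
        sub = sub[sub["day"].isin(days)]
    mat = sub.pivot_table(index=["stimulus", "day"], columns=["animal", "cell"],
                          values="delta_plus")
    if mat.isna().any().any():
        # A stimulus presented only on some days (e.g. forced CS trials)
        # yields all-NaN rows elsewhere, not holes within a row.
        full_rows = mat.dropna(how="any")
        holey = mat.drop(index=full_rows.index).dropna(how="all")
        if not holey.empty:
            raise ValueError(
                f"cells missing stimulus-day means for rows {list(holey.index)}")
        mat = full_rows
    return mat


def pcoa(distances: np.ndarray, d: int | str = "scree") -> EmbeddingResult:
    """Classical principal coordinates analysis of a distance matrix.

    Squared distances are double-centered, eigendecomposed, and
    coordinates are eigenvectors scaled by the square roots of the
    positive eigenvalues.  Negative eigenvalues are reported but their
    axes discarded.  ``d`` is either an explicit dimensionality or
    ``"scree"``: the elbow of the eigenvalue sequence (largest second
    difference), defaulting to 2 when the rule is ambiguous.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be nonnegative")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(eigval.max(), 0) * 1e-12
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])

    if d == "scree":
        chosen = _scree_dimension(eigval[pos])
    else:
        chosen = int(d)
    chosen = max(1, min(chosen, coords.shape[1])) if coords.shape[1] else 0
    return EmbeddingResult(
        objects=[], coordinates=coords, eigenvalues=eigval,
        d=chosen, orientation=np.ones(coords.shape[1]),
    )


def _scree_dimension(eigvals: np.ndarray) -> int:
    """Elbow of a descending eigenvalue sequence via the largest second
    difference; 2 when the sequence is too short or the maximum is tied."""
    if eigvals.size < 3:
        return min(2, eigvals.size)
    curvature = eigvals[:-2] - 2 * eigvals[1:-1] + eigvals[2:]
    peaks = np.flatnonzero(np.isclose(curvature, curvature.max()))
    if len(peaks) != 1:
        return 2
    return int(peaks[0]) + 1


def embed_population(
    vectors: pd.DataFrame,
    d: int | str = "scree",
    metric: str = "euclidean",
) -> EmbeddingResult:
    """PCoA of a population-vector matrix (rows = (stimulus, day))."""
    X = vectors.to_numpy()
    if metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=-1))
    elif metric == "correlation":
        C = np.corrcoef(X)
        D = np.sqrt(np.clip(1.0 - C, 0.0, None))
        np.fill_diagonal(D, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    emb = pcoa(D, d=d)
    emb.objects = [(str(s), str(day)) for s, day in vectors.index]
    return emb


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two coordinate vectors."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


def cs_divergence(
    emb: EmbeddingResult,
    days: list[str],
    cs_label: str = CS_LABEL,
    accepted: tuple[str, ...] = DEFAULT_ACCEPTED,
    aversive_label: str = AVERSIVE_LABEL,
) -> pd.DataFrame:
    """Per-day mean distance from the CS to the accepted stimuli.

    Returns one row per day with the mean CS-to-accepted distance and the
    companion CS-to-aversive distance, measured in the embedding's first
    ``emb.d`` dimensions.
    """
    accepted = tuple(s for s in accepted if s != cs_label)
    if not accepted:
        raise ValueError("accepted set is empty")
    rows = []
    for day in days:
        cs = emb.coords(cs_label, day)
        dists = [euclidean_distance(cs, emb.coords(s, day)) for s in accepted]
        rows.append({
            "day": day,
            "mean_accepted_distance": float(np.mean(dists)),
            "aversive_distance": euclidean_distance(cs, emb.coords(aversive_label, day)),
        })
    return pd.DataFrame(rows)


def orient_and_correlate(
    emb: EmbeddingResult,
    lick_means: dict[str, float],
    day: str,
) -> tuple[pd.Series, dict]:
    """Orient dimension 1 by lick behavior and quantify the correspondence.

    Flips the sign of dimension 1 (across the whole embedding) if needed
    so its correlation with mean licks is positive, then returns the
    oriented day coordinates and a dict with Pearson r, p, and the
    simple-regression slope/intercept/R^2.  With constant licks the
    correlation is undefined and all statistics are None.
    """
    dim1 = emb.dimension(0, day=day)
    stimuli = [s for (s, _) in dim1.index]
    if len(stimuli) < 3:
        raise ValueError("need at least 3 embedded stimuli")
    missing = [s for s in stimuli if s not in lick_means]
    if missing:
        raise ValueError(f"no lick means for {missing}")
    licks = np.array([lick_means[s] for s in stimuli])
    x = dim1.to_numpy()
    if np.ptp(licks) == 0 or np.ptp(x) == 0:
        return dim1, {"r": None, "p": None, "slope": None,
                      "intercept": None, "r_squared": None}
    r, _ = stats.pearsonr(x, licks)
    if r < 0:
        emb.coordinates[:, 0] *= -1
        emb.orientation[0] *= -1
        dim1 = emb.dimension(0, day=day)
        x = -x
    fit = stats.linregress(x, licks)
    return dim1, {"r": float(fit.rvalue), "p": float(fit.pvalue),
                  "slope": float(fit.slope), "intercept": float(fit.intercept),
                  "r_squared": float(fit.rvalue ** 2)}


def lw_complete_linkage(distances: np.ndarray) -> np.ndarray:
    """Agglomerative clustering via the Lance-Williams update with
    complete-linkage coefficients (a_i = a_j = 1/2, b = 0, g = 1/2).

    Returns a scipy-style merge array: one row per merge, ``[id_i, id_j,
    height, size]`` with new clusters numbered from ``n`` upward.
    """
    D = np.asarray(distances, dtype=float).copy()
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 objects")
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    dist = {(min(i, j), max(i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new = next_id
        next_id += 1
        merges.append([i, j, h, sizes[i] + sizes[j]])
        sizes[new] = sizes[i] + sizes[j]
        active.remove(i)
        active.remove(j)
        for k in active:
            d_ki = dist.pop((min(i, k), max(i, k)))
            d_kj = dist.pop((min(j, k), max(j, k)))
            # Lance-Williams, complete linkage: max(d_ki, d_kj)
            dist[(k, new)] = 0.5 * d_ki + 0.5 * d_kj + 0.5 * abs(d_ki - d_kj)
        del dist[(i, j)]
        active.append(new)
    return np.array(merges, dtype=float)
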