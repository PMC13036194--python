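import itertools

import numpy as np
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import cdist

from tastecoda import geometry as geo
from tastecoda.geometry import (
    cs_divergence,
    embed_population,
    euclidean_distance,
    lw_complete_linkage,
    orient_and_correlate,
    pcoa,
)


def _distances(points):
    return cdist(points, points)


class TestPCoA:
    def test_two_objects_at_distance_10(self):
        emb = pcoa(np.array([[0.0, 10.0], [10.0, 0.0]]))
        coords = emb.coordinates[:, 0]
        assert sorted(np.round(coords, 6)) == [-5.0, 5.0]

    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(7, 2))
        emb = pcoa(_distances(pts), d=2)
        _, _, disparity = procrustes(pts, emb.coordinates[:, :2])
        assert disparity < 1e-12

    def test_full_rank_reproduces_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(9, 4))
        D = _distances(pts)
        emb = pcoa(D)
        D2 = _distances(emb.coordinates)
        assert np.allclose(D, D2, rtol=1e-8, atol=1e-8)

    def test_coordinates_centered(self):
        rng = np.random.default_rng(2)
        emb = pcoa(_distances(rng.normal(size=(6, 3))))
        assert np.allclose(emb.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_eigenvalues_descending(self):
        rng = np.random.default_rng(3)
        emb = pcoa(_distances(rng.normal(size=(8, 3))))
        assert (np.diff(emb.eigenvalues) <= 1e-9).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 3))
        D = _distances(pts)
        perm = rng.permutation(6)
        emb1 = pcoa(D, d=2)
        emb2 = pcoa(D[np.ix_(perm, perm)], d=2)
        # permuting objects permutes coordinates (distances are invariant)
        d1 = _distances(emb1.coordinates)[np.ix_(perm, perm)]
        d2 = _distances(emb2.coordinates)
        assert np.allclose(d1, d2, atol=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            pcoa(np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_scree_prefers_clear_elbow(self):
        # two comparable strong dimensions, then a cliff to noise: the
        # largest second difference (elbow) sits at dimension 2
        rng = np.random.default_rng(5)
        pts = np.hstack([rng.normal(scale=10.0, size=(40, 1)),
                         rng.normal(scale=9.0, size=(40, 1)),
                         rng.normal(scale=0.05, size=(40, 5))])
        emb = pcoa(_distances(pts), d="scree")
        assert emb.d == 2


class TestEuclideanDistance:
    def test_three_four_five(self):
        assert euclidean_distance((0, 0), (3, 4)) == pytest.approx(5.0)

    def test_identical_points(self):
        assert euclidean_distance((1.5, -2.0), (1.5, -2.0)) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            euclidean_distance((0, 0), (1, 2, 3))

    def test_random_pairs_match_elementwise_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b = rng.normal(size=(2, 5))
            total = 0.0
            for x, y in zip(a, b):
                total += (x - y) ** 2
            assert euclidean_distance(a, b) == pytest.approx(total ** 0.5)


def naive_complete_linkage(D):
    """Brute-force oracle: recompute max linkage between member sets."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            h = max(D[a, b] for a in clusters[i] for b in clusters[j])
            if best is None or (h, (i, j)) < (best[2], (best[0], best[1])):
                best = (i, j, h)
        i, j, h = best
        merges.append([i, j, h, len(clusters[i]) + len(clusters[j])])
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return np.array(merges)


class TestLanceWilliams:
    def test_two_objects(self):
        Z = lw_complete_linkage(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert Z.shape == (1, 4)
        assert Z[0, 2] == 3.0

    def test_line_points(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        Z = lw_complete_linkage(_distances(pts))
        assert Z[0, :3].tolist() == [0.0, 1.0, 1.0]
        assert Z[1, 2] == 10.0

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(7)
        Z = lw_complete_linkage(_distances(rng.normal(size=(10, 3))))
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            D = _distances(rng.normal(size=(8, 3)))
            Z = lw_complete_linkage(D)
            Z0 = naive_complete_linkage(D)
            np.testing.assert_allclose(Z, Z0, atol=1e-10)

    def test_single_object_rejected(self):
        with pytest.raises(ValueError):
            lw_complete_linkage(np.zeros((1, 1)))


def _toy_embedding():
    """Hand-built embedding: 4 stimuli on one day, coordinates known."""
    import pandas as pd
    idx = pd.MultiIndex.from_product(
        [["sucrose", "NaCl", "QHCl_low", "QHCl_high"], ["d1"]],
        names=["stimulus", "day"])
    X = pd.DataFrame([[0.0, 0], [1.0, 0], [2.0, 0], [10.0, 0]],
                     index=idx, columns=["c1", "c2"])
    return embed_population(X, d=1)


class TestReadouts:
    def test_cs_divergence_zero_when_coincident(self):
        import pandas as pd
        idx = pd.MultiIndex.from_tuples(
            [(s, "d1") for s in ("NaCl", "sucrose", "QHCl_low", "QHCl_high")],
            names=["stimulus", "day"])
        X = pd.DataFrame([[1.0, 2.0]] * 3 + [[9.0, 9.0]], index=idx,
                         columns=["c1", "c2"])
        emb = embed_population(X, d=1)
        div = cs_divergence(emb, ["d1"], accepted=("sucrose", "QHCl_low"))
        assert div["mean_accepted_distance"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert div["aversive_distance"].iloc[0] > 1.0

    def test_orient_perfect_linear_licks(self):
        emb = _toy_embedding()
        licks = {"sucrose": 30.0, "NaCl": 27.0, "QHCl_low": 24.0, "QHCl_high": 0.0}
        _, fit = orient_and_correlate(emb, licks, "d1")
        assert fit["r"] == pytest.approx(1.0)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_orientation_flips_sign_for_negative_correlation(self):
        emb = _toy_embedding()
        licks = {"sucrose": 0.0, "NaCl": 5.0, "QHCl_low": 10.0, "QHCl_high": 40.0}
        before = emb.dimension(0, "d1").copy()
        dim1, fit = orient_and_correlate(emb, licks, "d1")
        assert fit["r"] > 0
        assert np.allclose(dim1.to_numpy(), -before.to_numpy())

    def test_constant_licks_undefined(self):
        emb = _toy_embedding()
        licks = {s: 10.0 for s in ("sucrose", "NaCl", "QHCl_low", "QHCl_high")}
        _, fit = orient_and_correlate(emb, licks, "d1")
        assert fit["r"] is None

    def test_missing_lick_mean_raises(self):
        emb = _toy_embedding()
        with pytest.raises(ValueError, match="lick"):
            orient_and_correlate(emb, {"sucrose": 1.0}, "d1")


class TestPopulationVectors:
    def test_shape_arithmetic(self, small_table):
        vec = geo.build_population_vectors(small_table.averaged, "CON")
        cfg_cells = 2 * 10  # animals x cells (small cohort)
        assert vec.shape == (7 * 3, cfg_cells)  # 7 stimuli x 3 days

    def test_matches_brute_force_assembly(self, small_table):
        vec = geo.build_population_vectors(small_table.averaged, "CON")
        trials = small_table.trials
        for (stim, day) in list(vec.index)[:5]:
            for (animal, cell) in list(vec.columns)[:4]:
                mask = ((trials["animal"] == animal) & (trials["cell"] == cell)
                        & (trials["day"] == day) & (trials["stimulus"] == stim)
                        & (trials["group"] == "CON"))
                expected = trials.loc[mask, "delta_plus"].mean()
                assert vec.loc[(stim, day), (animal, cell)] == pytest.approx(expected)

    def test_unknown_group_raises(self, small_table):
        with pytest.raises(ValueError, match="group"):
            geo.build_population_vectors(small_table.averaged, "NOPE")
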