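import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from microclubs import (DistanceMatrix, dispersion, pcoa, permanova,
                        unweighted_unifrac, weighted_unifrac)
from .conftest import euclidean_distance_matrix


class TestUnweightedUnifrac:
    def test_identity_zero(self, three_leaf_tree):
        assert unweighted_unifrac({"A", "B"}, {"A", "B"}, three_leaf_tree) == 0.0

    def test_disjoint_on_star_is_one(self, star_tree):
        assert unweighted_unifrac({"A", "B"}, {"C", "D"}, star_tree) == 1.0

    def test_hand_enumerated_cases(self, three_leaf_tree):
        assert unweighted_unifrac({"A", "B"}, {"C"}, three_leaf_tree) == 1.0
        assert unweighted_unifrac({"A", "B"}, {"A", "C"}, three_leaf_tree) \
            == pytest.approx(0.6)

    def test_symmetry_and_range(self, three_leaf_tree):
        sets = [{"A"}, {"B"}, {"A", "C"}, {"A", "B", "C"}]
        for a, b in itertools.combinations(sets, 2):
            d1 = unweighted_unifrac(a, b, three_leaf_tree)
            d2 = unweighted_unifrac(b, a, three_leaf_tree)
            assert d1 == d2 and 0.0 <= d1 <= 1.0

    def test_unknown_taxon_errors(self, three_leaf_tree):
        with pytest.raises(ValueError, match="Zz"):
            unweighted_unifrac({"A"}, {"Zz"}, three_leaf_tree)


class TestWeightedUnifrac:
    def test_identity_zero(self, star_tree):
        a = {"A": 0.5, "B": 0.5}
        assert weighted_unifrac(a, a, star_tree) == 0.0

    def test_all_mass_swap_normalized_is_one(self, star_tree):
        assert weighted_unifrac({"A": 1.0}, {"B": 1.0}, star_tree,
                                normalized=True) == pytest.approx(1.0)

    def test_symmetric(self, three_leaf_tree):
        a = {"A": 0.7, "B": 0.3}
        b = {"A": 0.2, "C": 0.8}
        assert weighted_unifrac(a, b, three_leaf_tree) \
            == weighted_unifrac(b, a, three_leaf_tree)

    def test_unnormalized_proportions_error(self, star_tree):
        with pytest.raises(ValueError, match="sum"):
            weighted_unifrac({"A": 0.7}, {"B": 1.0}, star_tree)


class TestPcoa:
    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(0)
        points = rng.standard_normal((10, 2))
        d = euclidean_distance_matrix(points)
        ordn = pcoa(DistanceMatrix([f"s{i}" for i in range(10)], d))
        recon = euclidean_distance_matrix(ordn.coordinates)
        assert np.abs(recon - d).max() < 1e-8
        assert ordn.imaginary_coordinates.shape[1] == 0

    def test_three_equidistant_simplex(self):
        d = np.ones((3, 3)) - np.eye(3)
        ordn = pcoa(DistanceMatrix(["a", "b", "c"], d))
        ev = ordn.eigenvalues
        assert ev[0] == pytest.approx(ev[1], rel=1e-9)
        assert abs(ev[2]) < 1e-12

    def test_duplicate_sample_coincides(self):
        points = np.array([[0.0, 0], [0, 0], [1, 0], [0, 2]])
        d = euclidean_distance_matrix(points)
        ordn = pcoa(DistanceMatrix(["a", "a2", "b", "c"], d))
        assert np.allclose(ordn.coordinates[0], ordn.coordinates[1], atol=1e-9)

    def test_eigenvalues_non_increasing_and_match_skbio(self):
        rng = np.random.default_rng(1)
        points = rng.standard_normal((8, 3))
        d = euclidean_distance_matrix(points)
        ordn = pcoa(DistanceMatrix([f"s{i}" for i in range(8)], d))
        assert (np.diff(ordn.eigenvalues) <= 1e-9).all()
        ref = skbio_pcoa(SkbioDM(d, [f"s{i}" for i in range(8)]))
        np.testing.assert_allclose(ordn.eigenvalues[:7],
                                   np.asarray(ref.eigvals)[:7], atol=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestPermanova:
    def _clusters(self):
        points = np.array([[0.0, 0], [0.1, 0], [0, 0.1],
                           [10, 10], [10.1, 10], [10, 10.1]])
        ids = [f"s{i}" for i in range(6)]
        return DistanceMatrix(ids, euclidean_distance_matrix(points))

    def test_separated_clusters_minimal_p(self):
        # large enough that no permutation reproduces the separating split
        rng = np.random.default_rng(3)
        points = np.vstack([rng.normal(0, 0.05, (12, 2)),
                            rng.normal(20, 0.05, (12, 2))])
        dm = DistanceMatrix([f"s{i}" for i in range(24)],
                            euclidean_distance_matrix(points))
        res = permanova(dm, ["a"] * 12 + ["b"] * 12, n_permutations=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_observed_f_is_maximal_by_enumeration(self):
        from microclubs.ordination import _permanova_f
        dm = self._clusters()
        d2 = dm.values ** 2
        obs = _permanova_f(d2, np.array([0, 0, 0, 1, 1, 1]), 2)
        for combo in itertools.combinations(range(6), 3):
            codes = np.ones(6, dtype=int)
            codes[list(combo)] = 0
            assert _permanova_f(d2, codes, 2) <= obs

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(5)
        points = rng.standard_normal((12, 3))
        labels = ["a"] * 6 + ["b"] * 6
        d = euclidean_distance_matrix(points)
        ids = [f"s{i}" for i in range(12)]
        mine = permanova(DistanceMatrix(ids, d), labels, n_permutations=99, seed=1)
        ref = skbio_permanova(SkbioDM(d, ids), grouping=labels, permutations=99)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_seed_determinism(self):
        dm = self._clusters()
        labels = ["a", "b", "a", "b", "a", "b"]
        r1 = permanova(dm, labels, 199, seed=42)
        r2 = permanova(dm, labels, 199, seed=42)
        assert r1.p_value == r2.p_value

    def test_singleton_group_errors(self):
        with pytest.raises(ValueError):
            permanova(self._clusters(), ["a", "a", "a", "a", "a", "b"], 99, 0)


class TestDispersion:
    def test_identical_samples_zero(self):
        points = np.array([[0.0, 0]] * 3 + [[5.0, 5], [6, 5], [5, 6]])
        d = euclidean_distance_matrix(points)
        ids = [f"s{i}" for i in range(6)]
        disp = dispersion(DistanceMatrix(ids, d), ["a"] * 3 + ["b"] * 3)
        assert disp["a"] == pytest.approx(0.0, abs=1e-8)

    def test_inflated_cluster_scales(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((10, 2))
        base -= base.mean(axis=0)
        points = np.vstack([base, 3.0 * base + 50.0])
        d = euclidean_distance_matrix(points)
        ids = [f"s{i}" for i in range(20)]
        disp = dispersion(DistanceMatrix(ids, d), ["a"] * 10 + ["b"] * 10)
        assert disp["b"] == pytest.approx(3.0 * disp["a"], rel=1e-6)

    def test_centroid_equals_median_for_symmetric_sets(self):
        pts = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1],
                        [9.0, 0], [11, 0], [10, 1], [10, -1]])
        d = euclidean_distance_matrix(pts)
        ids = [f"s{i}" for i in range(8)]
        labels = ["a"] * 4 + ["b"] * 4
        med = dispersion(DistanceMatrix(ids, d), labels, center="median")
        cen = dispersion(DistanceMatrix(ids, d), labels, center="centroid")
        for g in ("a", "b"):
            assert med[g] == pytest.approx(cen[g], abs=1e-6)

    def test_singleton_group_errors(self):
        d = euclidean_distance_matrix(np.arange(8.0).reshape(4, 2))
        with pytest.raises(ValueError):
            dispersion(DistanceMatrix(list("abcd"), d), ["x", "x", "x", "y"])


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1], [2, 0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(["a", "b"], np.array([[1.0, 1], [1, 1.0]]))
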