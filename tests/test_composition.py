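"""CLR/Aitchison contracts, PCA isometry, PERMANOVA/dispersion/RDA oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from seedtrace import (
    ClrTable,
    DistanceMatrix,
    EnvTable,
    FeatureTable,
    aitchison_distance,
    clr_transform,
    dispersion_test,
    pca,
    permanova,
    rda_marginal_test,
)
from seedtrace.composition import permanova_exhaustive

from conftest import random_count_table


def _clr_of(cols, pc=0.0):
    arr = np.array(cols).T
    t = FeatureTable(
        [f"f{i}" for i in range(arr.shape[0])],
        [f"s{j}" for j in range(arr.shape[1])],
        arr,
    )
    return clr_transform(t, pc)


class TestClr:
    def test_equal_parts_map_to_zero(self):
        c = _clr_of([[1, 1, 1, 1]])
        assert np.allclose(c.values, 0.0)

    def test_two_part_hand_value(self):
        c = _clr_of([[2, 8]])
        assert c.values[:, 0] == pytest.approx([-0.6931, 0.6931], abs=1e-4)

    def test_scale_invariance_zero_free(self):
        x = [[2, 8, 5]]
        c1 = _clr_of(x)
        c2 = _clr_of([[20, 80, 50]])
        assert np.allclose(c1.values, c2.values)

    def test_columns_sum_to_zero(self):
        rng = np.random.default_rng(0)
        t = random_count_table(rng, 30, 10)
        c = clr_transform(t, 0.5)
        assert np.abs(c.values.sum(axis=0)).max() < 1e-9

    def test_zero_counts_need_pseudocount(self):
        t = FeatureTable(["a", "b"], ["s"], np.array([[0], [5]]))
        with pytest.raises(ValueError, match="pseudocount"):
            clr_transform(t, 0.0)


class TestAitchison:
    def test_self_distance_zero_and_symmetry(self):
        rng = np.random.default_rng(1)
        c = clr_transform(random_count_table(rng, 20, 6), 0.5)
        d = aitchison_distance(c)
        assert np.allclose(np.diag(d.data), 0.0)
        assert np.allclose(d.data, d.data.T)

    def test_hand_value_mirror_composition(self):
        d = aitchison_distance(_clr_of([[2, 8], [8, 2]]))
        assert d.data[0, 1] == pytest.approx(math.log(4) * math.sqrt(2), abs=1e-9)
        assert d.data[0, 1] == pytest.approx(1.9605, abs=1e-3)

    def test_invariant_to_per_sample_scaling(self):
        d1 = aitchison_distance(_clr_of([[2, 8, 5], [1, 3, 9]]))
        d2 = aitchison_distance(_clr_of([[20, 80, 50], [3, 9, 27]]))
        assert np.allclose(d1.data, d2.data)

    def test_perturbation_invariance(self):
        # multiplying every sample by the same per-feature factors (an
        # Aitchison perturbation) shifts all CLR columns by one constant
        # vector -> no CLR difference between samples changes, no distance
        d1 = aitchison_distance(_clr_of([[2, 8, 5], [4, 1, 10]]))
        d2 = aitchison_distance(_clr_of([[2 * 3, 8 * 7, 5 * 2], [4 * 3, 1 * 7, 10 * 2]]))
        assert np.allclose(d1.data, d2.data, atol=1e-9)


class TestPca:
    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        res = pca(clr_transform(random_count_table(rng, 25, 8), 0.5))
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_data_loads_on_first_axis(self):
        v = np.array([1.0, -2.0, 1.0])
        X = np.outer(v, [1.0, 2.0, 3.0, 4.0])
        c = ClrTable([f"f{i}" for i in range(3)], [f"s{j}" for j in range(4)], X, 0.0)
        res = pca(c)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_isometry_with_aitchison_distance(self):
        rng = np.random.default_rng(3)
        c = clr_transform(random_count_table(rng, 30, 9), 0.5)
        res = pca(c)
        d_scores = squareform(pdist(res.scores))
        d_ait = aitchison_distance(c).data
        assert np.abs(d_scores - d_ait).max() < 1e-8

    def test_constant_data_rejected(self):
        c = ClrTable(["f0", "f1"], ["s0", "s1"], np.zeros((2, 2)), 0.0)
        with pytest.raises(ValueError, match="constant"):
            pca(c)


def _points_distance(X):
    ids = [f"s{i}" for i in range(len(X))]
    return DistanceMatrix(ids, squareform(pdist(X)))


class TestPermanova:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (6, 2))
        X[3:] += 1.0
        d = _points_distance(X)
        labels = ["A"] * 3 + ["B"] * 3
        p_exact = permanova_exhaustive(d, labels)
        res = permanova(d, labels, n_permutations=9999, seed=1)
        assert abs(res.p - p_exact) < 0.01

    def test_ss_decomposition(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (12, 3))
        d = _points_distance(X)
        res = permanova(d, ["A"] * 6 + ["B"] * 6, n_permutations=99, seed=0)
        assert res.ss_total == pytest.approx(res.ss_between + res.ss_within, abs=1e-9)

    def test_ss_total_equals_deviations_from_grand_centroid(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (10, 4))
        d = _points_distance(X)
        res = permanova(d, ["A"] * 5 + ["B"] * 5, n_permutations=99, seed=0)
        centered = X - X.mean(axis=0)
        assert res.ss_total == pytest.approx((centered**2).sum(), abs=1e-8)

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (12, 4))
        X[:6] += 0.8
        d = _points_distance(X)
        labels = ["A"] * 6 + ["B"] * 6
        ours = permanova(d, labels, n_permutations=999, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.data, d.sample_ids), grouping=labels, permutations=999
        )
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_identical_groups_give_null_p(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 1, (4, 2))
        X = np.vstack([pts, pts])  # two groups, identical point multisets
        d = _points_distance(X)
        res = permanova(d, ["A"] * 4 + ["B"] * 4, n_permutations=999, seed=0)
        assert res.R2 < 0.05
        assert res.p > 0.2

    def test_perfect_separation_forces_r2_one(self):
        X = np.vstack([np.zeros((3, 2)), np.ones((3, 2))])
        d = _points_distance(X)
        res = permanova(d, ["A"] * 3 + ["B"] * 3, n_permutations=999, seed=0)
        assert res.R2 == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_matched_reordering(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (10, 3))
        X[5:] += 1.0
        d = _points_distance(X)
        labels = ["A"] * 5 + ["B"] * 5
        perm = rng.permutation(10)
        d2 = d.reorder([d.sample_ids[i] for i in perm])
        labels2 = [labels[i] for i in perm]
        r1 = permanova(d, labels, n_permutations=999, seed=3)
        r2 = permanova(d2, labels2, n_permutations=999, seed=3)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, abs=1e-10)
        assert r1.R2 == pytest.approx(r2.R2, abs=1e-10)

    def test_singleton_group_rejected(self):
        X = np.random.default_rng(0).normal(0, 1, (4, 2))
        d = _points_distance(X)
        with pytest.raises(ValueError, match="single sample"):
            permanova(d, ["A", "B", "B", "B"], n_permutations=99, seed=0)


class TestDispersion:
    def test_all_identical_points(self):
        X = np.zeros((6, 3))
        c = ClrTable([f"f{i}" for i in range(3)], [f"s{j}" for j in range(6)], X.T, 0.0)
        res = dispersion_test(c, ["A"] * 3 + ["B"] * 3, n_permutations=199, seed=0)
        assert np.allclose(res.distances_to_centroid, 0.0)
        assert res.p == 1.0

    def test_mirror_groups_have_equal_dispersion(self):
        rng = np.random.default_rng(9)
        A = rng.normal(0, 1, (8, 3))
        B = -A  # same internal geometry
        X = np.vstack([A, B])
        X = (X - X.mean(axis=0)).T
        X = X - X.mean(axis=0, keepdims=True)  # columns sum to 0
        c = ClrTable([f"f{i}" for i in range(3)], [f"s{j}" for j in range(16)], X, 0.0)
        res = dispersion_test(c, ["A"] * 8 + ["B"] * 8, n_permutations=199, seed=0)
        assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_distance_matrix_route_matches_clr_route(self):
        rng = np.random.default_rng(10)
        t = random_count_table(rng, 20, 10)
        c = clr_transform(t, 0.5)
        labels = ["A"] * 5 + ["B"] * 5
        r1 = dispersion_test(c, labels, n_permutations=199, seed=5)
        r2 = dispersion_test(aitchison_distance(c), labels, n_permutations=199, seed=5)
        assert np.allclose(r1.distances_to_centroid, r2.distances_to_centroid, atol=1e-8)
        assert r1.p == r2.p

    def test_detects_unequal_dispersion(self):
        rng = np.random.default_rng(11)
        XA = rng.normal(0, 3, (20, 5))
        XB = rng.normal(0, 1, (20, 5))
        X = np.vstack([XA, XB]).T
        X = X - X.mean(axis=0, keepdims=True)
        c = ClrTable([f"f{i}" for i in range(5)], [f"s{j}" for j in range(40)], X, 0.0)
        res = dispersion_test(c, ["A"] * 20 + ["B"] * 20, n_permutations=999, seed=0)
        assert res.p < 0.05
        assert res.group_means["A"] > res.group_means["B"]


class TestRda:
    def _setup(self, seed=5, n=10):
        rng = np.random.default_rng(seed)
        t = random_count_table(rng, 12, n)
        return clr_transform(t, 0.5)

    def test_binary_variable_equals_permanova_r2(self):
        clr = self._setup()
        labels = ["A"] * 5 + ["B"] * 5
        env = EnvTable(pd.DataFrame({"x": [0.0] * 5 + [1.0] * 5}, index=clr.sample_ids))
        res = rda_marginal_test(clr, env, "x", n_permutations=99, seed=0)
        pr = permanova(aitchison_distance(clr), labels, n_permutations=99, seed=0)
        assert res["constrained_fraction"] == pytest.approx(pr.R2, abs=1e-8)

    def test_exact_linear_driver_leaves_no_residual(self):
        n = 8
        x = np.linspace(-1, 1, n)
        load = np.array([1.0, -0.5, -0.5])
        X = np.outer(load, x)  # features x samples, columns sum to 0
        c = ClrTable(["f0", "f1", "f2"], [f"s{j}" for j in range(n)], X, 0.0)
        env = EnvTable(pd.DataFrame({"x": x}, index=c.sample_ids))
        res = rda_marginal_test(c, env, "x", n_permutations=199, seed=0)
        assert res["constrained_fraction"] == pytest.approx(1.0, abs=1e-9)
        assert res["p"] == pytest.approx(1 / 200, abs=1e-9)

    def test_shuffled_driver_is_null(self):
        # permuting a real driver breaks the link: p should be ~uniform
        rng = np.random.default_rng(21)
        pvals = []
        for rep in range(20):
            clr = self._setup(seed=100 + rep, n=12)
            x = rng.permutation(np.linspace(0, 1, 12))
            env = EnvTable(pd.DataFrame({"x": x}, index=clr.sample_ids))
            pvals.append(rda_marginal_test(clr, env, "x", 199, seed=rep)["p"])
        assert 0.15 < np.mean(pvals) < 0.85

    def test_constant_variable_rejected(self):
        clr = self._setup()
        env = EnvTable(pd.DataFrame({"x": [1.0] * 10}, index=clr.sample_ids))
        with pytest.raises(ValueError, match="constant"):
            rda_marginal_test(clr, env, "x", 99, seed=0)
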