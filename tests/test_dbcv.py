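"""Unit and property tests for the DBCV core quantities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dbcvkit import (
    DegenerateClusterError,
    InsufficientClustersError,
    UndefinedValidityError,
    apcd_values,
    cluster_validity,
    dbcv_index,
    dbcv_score,
    density_separation,
    density_sparseness,
    mutual_reachability,
    reachability_graph,
)
from dbcvkit.exceptions import DbcvError

from _reference import naive_dbcv


class TestApcd:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ([[0.0], [1.0]], [1.0, 1.0]),  # single neighbour at distance 1
            # equilateral triangle, side 1: all neighbour distances equal
            (
                [[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3) / 2]],
                [1.0, 1.0, 1.0],
            ),
            # unit-square corners: mean(1, 1, 1/2) = 5/6, then power -1/2
            (
                [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]],
                [math.sqrt(6 / 5)] * 4,
            ),
        ],
    )
    def test_worked_examples(self, points, expected):
        np.testing.assert_allclose(apcd_values(points), expected, atol=1e-12)

    def test_coincident_points_limit_to_zero(self):
        # duplicated coordinates make a (1/0)^d term; the limit is APCD = 0
        apcd = apcd_values([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        assert apcd[0] == 0.0 and apcd[1] == 0.0
        assert np.isfinite(apcd[2]) and apcd[2] > 0

    def test_all_coincident_cluster(self):
        np.testing.assert_array_equal(apcd_values([[2.0], [2.0], [2.0]]), 0.0)

    def test_equal_pairwise_distances_collapse_to_common_value(self):
        # when every within-cluster distance equals c, APCD = c
        c = 3.7
        pts = np.array([[0.0], [c]])
        np.testing.assert_allclose(apcd_values(pts), c, atol=1e-12)

    def test_singleton_cluster_rejected(self):
        with pytest.raises(DegenerateClusterError):
            apcd_values([[0.0, 0.0]])

    def test_explicit_dimension_exponent(self):
        # with d=1 on 2-D square corners the generalized mean changes
        sq = [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]
        expected = 1.0 / ((1 + 1 + 1 / math.sqrt(2)) / 3)
        np.testing.assert_allclose(apcd_values(sq, d=1), expected, atol=1e-12)


class TestMutualReachability:
    @pytest.mark.parametrize(
        "a, b, e, expected", [(1, 1, 10, 10), (3, 2, 1, 3), (0, 0, 0, 0)]
    )
    def test_max_of_three(self, a, b, e, expected):
        assert mutual_reachability(a, b, e) == expected

    @given(
        st.floats(0, 1e6), st.floats(0, 1e6), st.floats(0, 1e6)
    )
    def test_symmetry_and_dominance(self, a, b, e):
        assert mutual_reachability(a, b, e) == mutual_reachability(b, a, e)
        assert mutual_reachability(a, b, e) >= e

    def test_negative_input_rejected(self):
        with pytest.raises(DbcvError):
            mutual_reachability(-1.0, 0.0, 1.0)


class TestReachabilityGraph:
    def test_mrd_dominates_euclid_symmetric_zero_diagonal(self, make_instance):
        rng = np.random.default_rng(7)
        X, y = make_instance(rng)
        clusters = [np.flatnonzero(y == c) for c in np.unique(y[y != -1])]
        g = reachability_graph(X, clusters)
        assert np.all(g.mrd >= g.euclid - 1e-15)
        np.testing.assert_allclose(g.mrd, g.mrd.T)
        np.testing.assert_array_equal(np.diag(g.mrd), 0.0)


class TestDensitySparseness:
    def test_two_point_cluster_single_edge(self):
        g = reachability_graph(np.array([[0.0], [1.0]]), [np.array([0, 1])])
        assert density_sparseness([0, 1], g) == 1.0

    def test_three_point_line_hand_computed(self):
        # APCDs (1.5, 4/3, 2.4); MRDs (1.5, 2.4, 3.0); MST keeps 1.5 and 2.4
        g = reachability_graph(np.array([[0.0], [1.0], [3.0]]), [np.arange(3)])
        assert density_sparseness([0, 1, 2], g) == pytest.approx(2.4, abs=1e-12)

    def test_member_order_irrelevant(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        g = reachability_graph(pts, [np.arange(12)])
        ref = density_sparseness(np.arange(12), g)
        for _ in range(5):
            perm = rng.permutation(12)
            assert density_sparseness(perm, g) == pytest.approx(ref, abs=1e-12)

    def test_internal_mode_never_exceeds_literal(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(30, 2))
        g = reachability_graph(pts, [np.arange(30)])
        lit = density_sparseness(np.arange(30), g, mode="all")
        strict = density_sparseness(np.arange(30), g, mode="internal")
        assert strict <= lit

    def test_internal_mode_falls_back_on_tiny_clusters(self):
        g = reachability_graph(np.array([[0.0], [1.0]]), [np.array([0, 1])])
        assert density_sparseness([0, 1], g, mode="internal") == 1.0


class TestDensitySeparation:
    def test_separated_line_clusters(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        g = reachability_graph(pts, [np.array([0, 1]), np.array([2, 3])])
        assert density_separation([0, 1], [2, 3], g) == 9.0

    def test_coincident_clusters_reach_zero(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        g = reachability_graph(pts, [np.array([0, 1]), np.array([2, 3])])
        assert density_separation([0, 1], [2, 3], g) == 0.0

    def test_symmetry_on_random_instances(self, make_instance):
        rng = np.random.default_rng(5)
        for _ in range(10):
            X, y = make_instance(rng, n_max=25)
            labs = np.unique(y[y != -1])
            ca, cb = np.flatnonzero(y == labs[0]), np.flatnonzero(y == labs[1])
            g = reachability_graph(X, [np.flatnonzero(y == c) for c in labs])
            assert density_separation(ca, cb, g) == density_separation(cb, ca, g)

    def test_same_cluster_twice_rejected(self):
        pts = np.array([[0.0], [1.0], [5.0], [6.0]])
        g = reachability_graph(pts, [np.array([0, 1]), np.array([2, 3])])
        with pytest.raises(DbcvError):
            density_separation([0, 1], [0, 1], g)


class TestClusterValidity:
    @pytest.mark.parametrize(
        "dsc, dspc, expected",
        [(1, 10, 0.9), (3.3, 3.3, 0.0), (10, 1, -0.9)],
    )
    def test_worked_examples(self, dsc, dspc, expected):
        assert cluster_validity(dsc, dspc) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_zero_zero(self):
        with pytest.raises(UndefinedValidityError):
            cluster_validity(0.0, 0.0)


FOUR_POINTS = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
FOUR_LABELS = np.array([0, 0, 1, 1])


class TestDbcvIndex:
    def test_two_cluster_micro_example(self):
        # APCDs all 1, DSC 1 per cluster, DSPC 10, VC 0.9, weights 1/2
        bd = dbcv_index(FOUR_POINTS, FOUR_LABELS)
        assert bd.overall == pytest.approx(0.9, abs=1e-12)
        for c in bd.clusters:
            assert c.vc == pytest.approx(0.9, abs=1e-12)
            assert c.weight == 0.5

    def test_noise_shrinks_weights_not_validity(self):
        noise_pts = np.array([[50.0, 50.0], [60.0, -60.0], [-50.0, 5.0], [0.0, 80.0]])
        pts = np.vstack([FOUR_POINTS, noise_pts])
        labels = np.concatenate([FOUR_LABELS, [-1] * 4])
        bd = dbcv_index(pts, labels)
        assert bd.overall == pytest.approx(0.45, abs=1e-12)
        assert bd.n_noise == 4
        for c in bd.clusters:
            assert c.vc == pytest.approx(0.9, abs=1e-12)
            assert c.weight == pytest.approx(2 / 8)

    def test_single_cluster_rejected(self):
        with pytest.raises(InsufficientClustersError):
            dbcv_index(FOUR_POINTS, np.zeros(4, dtype=int))

    def test_all_noise_rejected(self):
        with pytest.raises(InsufficientClustersError):
            dbcv_index(FOUR_POINTS, np.full(4, -1))

    def test_singleton_policy(self):
        pts = np.vstack([FOUR_POINTS, [[30.0, 30.0]]])
        labels = np.array([0, 0, 1, 1, 2])
        with pytest.raises(DegenerateClusterError):
            dbcv_index(pts, labels)
        bd = dbcv_index(pts, labels, singletons="noise")
        assert bd.n_noise == 1
        assert {c.label for c in bd.clusters} == {0, 1}

    def test_weight_conservation(self, make_instance):
        rng = np.random.default_rng(17)
        for _ in range(20):
            X, y = make_instance(rng)
            bd = dbcv_index(X, y)
            total = sum(c.weight for c in bd.clusters)
            assert total == pytest.approx((len(y) - bd.n_noise) / len(y), abs=1e-12)

    def test_breakdown_recomposes_overall(self, make_instance):
        rng = np.random.default_rng(19)
        X, y = make_instance(rng)
        bd = dbcv_index(X, y)
        assert bd.overall == pytest.approx(
            sum(c.weight * c.vc for c in bd.clusters), abs=1e-15
        )

    def test_labels_length_mismatch(self):
        with pytest.raises(DbcvError):
            dbcv_index(FOUR_POINTS, [0, 0, 1])


class TestInvariances:
    def test_bounds_on_random_suite(self, make_instance):
        rng = np.random.default_rng(23)
        for _ in range(30):
            X, y = make_instance(rng)
            for kw in ({}, {"dsc_mode": "internal", "dspc_mode": "internal"}):
                bd = dbcv_index(X, y, **kw)
                assert -1.0 <= bd.overall <= 1.0
                assert all(-1.0 <= c.vc <= 1.0 for c in bd.clusters)

    @pytest.mark.parametrize("c", [0.01, 1.0, 100.0])
    def test_scale_invariance(self, make_instance, c):
        rng = np.random.default_rng(29)
        for _ in range(5):
            X, y = make_instance(rng, n_max=30)
            ref = dbcv_index(X, y)
            scaled = dbcv_index(c * X, y)
            assert scaled.overall == pytest.approx(ref.overall, abs=1e-9)
            # intermediate quantities scale linearly
            for a, b in zip(ref.clusters, scaled.clusters):
                assert b.dsc == pytest.approx(c * a.dsc, rel=1e-9)
                assert b.min_dspc == pytest.approx(c * a.min_dspc, rel=1e-9)

    def test_rigid_motion_invariance(self, make_instance):
        rng = np.random.default_rng(31)
        X, y = make_instance(rng, n_max=30, d_max=2)
        if X.shape[1] == 1:
            X = np.hstack([X, np.zeros_like(X)])
        theta = 0.73
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = X @ R.T + np.array([5.0, -3.0])
        assert dbcv_score(moved, y) == pytest.approx(dbcv_score(X, y), abs=1e-9)

    def test_permutation_and_relabel_invariance(self, make_instance):
        rng = np.random.default_rng(37)
        X, y = make_instance(rng)
        ref = dbcv_score(X, y)
        perm = rng.permutation(len(y))
        assert dbcv_score(X[perm], y[perm]) == pytest.approx(ref, abs=1e-9)
        remap = {c: 100 - c for c in np.unique(y[y != -1])}
        y2 = np.array([remap.get(v, -1) for v in y])
        assert dbcv_score(X, y2) == pytest.approx(ref, abs=1e-9)

    def test_separation_monotonicity(self):
        # translating one cluster rigidly away never decreases the index
        rng = np.random.default_rng(41)
        a = rng.normal(0, 0.5, (15, 2))
        b = rng.normal(0, 0.5, (15, 2)) + [4.0, 0.0]
        labels = np.repeat([0, 1], 15)
        scores = []
        for extra in (0.0, 1.0, 3.0, 10.0, 50.0):
            pts = np.vstack([a, b + [extra, 0.0]])
            scores.append(dbcv_score(pts, labels))
        assert all(s2 >= s1 - 1e-12 for s1, s2 in zip(scores, scores[1:]))


class TestNaiveEquivalence:
    @pytest.mark.parametrize("mode", ["all", "internal"])
    def test_matches_brute_force_reference(self, make_instance, mode):
        rng = np.random.default_rng(43)
        for _ in range(25):
            X, y = make_instance(rng, n_max=25)
            fast = dbcv_score(X, y, dsc_mode=mode, dspc_mode=mode)
            slow = naive_dbcv(X, y, dsc_mode=mode, dspc_mode=mode)
            assert fast == pytest.approx(slow, abs=1e-9)
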