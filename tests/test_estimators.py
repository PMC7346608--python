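import itertools
import math

import numpy as np
import pytest

from qpcrfit import (
    GrowthPoint,
    OutlierZone,
    estimate_pairwise,
    fit_differences_gls,
    fit_differences_naive,
    fit_direct,
    flag_outlier_zone,
    make_difference_pairs,
    max_disjoint_pairs,
    pairwise_ratio_estimates,
    pairwise_sigma_weights,
    weighted_mean_pairwise,
)
from qpcrfit.exceptions import (
    DegenerateDesignError,
    DisconnectedPairsError,
    SingularGramError,
)


def _chain_subset(diffs):
    """Rows (i, i+1): a spanning tree over consecutive point indices."""
    idx = [k for k, (a, b) in enumerate(diffs.rows) if b == a + 1]
    return diffs.subset(idx)


# ---------------------------------------------------------------------------
# fit_direct
# ---------------------------------------------------------------------------


class TestFitDirect:
    def test_exact_recovery_noiseless(self, noiseless_points, design):
        res = fit_direct(noiseless_points, D=2.0)
        assert res.converged
        assert res.E_hat == pytest.approx(1.85, abs=1e-12)
        assert res.y0_hat == pytest.approx(design.params.y0, rel=1e-10)
        assert res.chisq == pytest.approx(0.0, abs=1e-18)
        assert res.nu == 7

    def test_se_matches_finite_difference_jacobian_oracle(self, noisy_points):
        res = fit_direct(noisy_points, D=2.0)
        assert abs(res.E_hat - 1.85) < 4 * res.se_E

        # independent covariance oracle: central finite-difference Jacobian
        x = np.array([p.x for p in noisy_points], float)
        j = np.array([p.j for p in noisy_points], float)

        def model(y0, E):
            return y0 * E**x / 2.0**j

        h_y0 = res.y0_hat * 1e-6
        h_E = res.E_hat * 1e-6
        J = np.column_stack(
            [
                (model(res.y0_hat + h_y0, res.E_hat) - model(res.y0_hat - h_y0, res.E_hat))
                / (2 * h_y0),
                (model(res.y0_hat, res.E_hat + h_E) - model(res.y0_hat, res.E_hat - h_E))
                / (2 * h_E),
            ]
        )
        cov_oracle = res.s_y**2 * np.linalg.inv(J.T @ J)
        assert res.se_E == pytest.approx(math.sqrt(cov_oracle[1, 1]), rel=1e-6)
        assert res.se_y0 == pytest.approx(math.sqrt(cov_oracle[0, 0]), rel=1e-6)

    def test_single_cycle_design_is_degenerate(self):
        pts = [GrowthPoint(0, 0, 15, y) for y in (50.0, 51.0, 52.0)]
        with pytest.raises(DegenerateDesignError, match="single cycle"):
            fit_direct(pts, D=2.0)

    def test_too_few_points(self):
        pts = [GrowthPoint(0, 0, 14, 50.0), GrowthPoint(0, 0, 15, 90.0)]
        with pytest.raises(DegenerateDesignError):
            fit_direct(pts, D=2.0)

    def test_cov_symmetric_psd(self, noisy_points):
        res = fit_direct(noisy_points, D=2.0)
        np.testing.assert_allclose(res.cov, res.cov.T)
        assert np.all(np.linalg.eigvalsh(res.cov) >= -1e-18)


# ---------------------------------------------------------------------------
# differences
# ---------------------------------------------------------------------------


class TestMakeDifferencePairs:
    def test_nine_points_give_36_rows(self, noiseless_points):
        diffs = make_difference_pairs(noiseless_points)
        assert len(diffs.rows) == 36

    def test_two_points(self):
        pts = [GrowthPoint(0, 0, 14, 50.0), GrowthPoint(0, 0, 15, 90.0)]
        diffs = make_difference_pairs(pts)
        assert diffs.rows == [(0, 1)]
        np.testing.assert_array_equal(diffs.L, [[1.0, -1.0]])

    def test_rank_oracle(self, noiseless_points):
        diffs = make_difference_pairs(noiseless_points)
        assert np.linalg.matrix_rank(diffs.L) == 8

    def test_rows_sum_to_zero_and_d_consistent(self, noisy_points):
        diffs = make_difference_pairs(noisy_points)
        np.testing.assert_allclose(diffs.L.sum(axis=1), 0.0)
        y = np.array([p.y for p in noisy_points])
        np.testing.assert_allclose(diffs.d, diffs.L @ y)

    def test_lexicographic_order(self, noisy_points):
        diffs = make_difference_pairs(noisy_points)
        assert diffs.rows == sorted(diffs.rows)
        assert all(a < b for a, b in diffs.rows)


class TestFitDifferencesNaive:
    def test_exact_noiseless(self, noiseless_points):
        diffs = make_difference_pairs(noiseless_points)
        res = fit_differences_naive(diffs, noiseless_points, D=2.0)
        assert res.E_hat == pytest.approx(1.85, abs=1e-10)
        assert res.chisq == pytest.approx(0.0, abs=1e-16)
        assert res.n_obs == 36

    def test_apparent_se_smaller_than_direct(self, noisy_points):
        direct = fit_direct(noisy_points, D=2.0)
        diffs = make_difference_pairs(noisy_points)
        naive = fit_differences_naive(diffs, noisy_points, D=2.0)
        assert naive.se_E < direct.se_E
        # the fallacious shrinkage is close to the independent-data factor ~1.9
        assert 1.4 < direct.se_E / naive.se_E < 2.6

    def test_too_few_points(self):
        pts = [GrowthPoint(0, 0, 14, 50.0), GrowthPoint(0, 0, 15, 90.0)]
        diffs = make_difference_pairs(pts)
        with pytest.raises(DegenerateDesignError):
            fit_differences_naive(diffs, pts, D=2.0)


class TestFitDifferencesGLS:
    def test_equals_direct_fit(self, noisy_points):
        direct = fit_direct(noisy_points, D=2.0)
        diffs = _chain_subset(make_difference_pairs(noisy_points))
        gls = fit_differences_gls(diffs, anchor=0, points=noisy_points, D=2.0)
        assert gls.E_hat == pytest.approx(direct.E_hat, rel=1e-8)
        assert gls.y0_hat == pytest.approx(direct.y0_hat, rel=1e-8)
        assert gls.se_E == pytest.approx(direct.se_E, rel=1e-8)
        assert gls.se_y0 == pytest.approx(direct.se_y0, rel=1e-8)

    def test_nine_rows_singular(self, noisy_points):
        diffs = make_difference_pairs(noisy_points)
        nine = diffs.subset(range(9))
        with pytest.raises(SingularGramError, match="det"):
            fit_differences_gls(nine, anchor=0, points=noisy_points, D=2.0)

    def test_all_36_rows_singular(self, noisy_points):
        diffs = make_difference_pairs(noisy_points)
        with pytest.raises(SingularGramError):
            fit_differences_gls(diffs, anchor=0, points=noisy_points, D=2.0)

    def test_non_spanning_rows(self, noisy_points):
        diffs = make_difference_pairs(noisy_points)
        # 8 rows confined to points 0..7: point 8 never sampled
        idx = [k for k, (a, b) in enumerate(diffs.rows) if b <= 7][:8]
        sub = diffs.subset(idx)
        assert len(sub.rows) == 8
        with pytest.raises(DisconnectedPairsError):
            fit_differences_gls(sub, anchor=0, points=noisy_points, D=2.0)

    @pytest.mark.parametrize("anchor", [0, 4, 8])
    @pytest.mark.parametrize("tree_seed", [0, 1, 2])
    def test_random_spanning_trees_and_anchors(self, noisy_points, anchor, tree_seed):
        rng = np.random.default_rng(tree_seed)
        diffs = make_difference_pairs(noisy_points)
        # random spanning tree via randomized Kruskal
        order = rng.permutation(len(diffs.rows))
        parent = list(range(9))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        chosen = []
        for k in order:
            a, b = diffs.rows[k]
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
                chosen.append(int(k))
            if len(chosen) == 8:
                break
        sub = diffs.subset(chosen)
        direct = fit_direct(noisy_points, D=2.0)
        gls = fit_differences_gls(sub, anchor=anchor, points=noisy_points, D=2.0)
        for attr in ("E_hat", "y0_hat", "se_E", "se_y0"):
            assert getattr(gls, attr) == pytest.approx(getattr(direct, attr), rel=1e-8)


# ---------------------------------------------------------------------------
# pairwise ratio estimator
# ---------------------------------------------------------------------------


class TestPairwiseRatios:
    def test_same_curve_noiseless_pair(self):
        y0, E = 0.04, 1.85
        pts = [
            GrowthPoint(0, 0, 14, y0 * E**14),
            GrowthPoint(0, 0, 16, y0 * E**16),
            GrowthPoint(0, 0, 15, y0 * E**15),
        ]
        ests = pairwise_ratio_estimates(pts[:2])
        assert len(ests) == 1
        assert ests[0].E_ij == pytest.approx(1.85, rel=1e-12)

    def test_cross_curve_dilution_correction(self):
        y0, E, D = 0.04, 1.85, 2.0
        pts = [
            GrowthPoint(0, 0, 15, y0 * E**15),
            GrowthPoint(1, 1, 17, y0 * E**17 / D),
            GrowthPoint(2, 2, 18, y0 * E**18 / D**2),
        ]
        ests = pairwise_ratio_estimates(pts[:2])
        assert ests[0].E_ij == pytest.approx(1.85, rel=1e-12)

    def test_default_layout_count_31(self, noiseless_points):
        """Brute-force enumeration oracle for the same-cycle exclusions."""
        ests = pairwise_ratio_estimates(noiseless_points)
        xs = [p.x for p in noiseless_points]
        n_equal = sum(
            1 for a, b in itertools.combinations(range(9), 2) if xs[a] == xs[b]
        )
        assert n_equal == 5
        assert len(ests) == 36 - n_equal == 31

    def test_orientation(self, noisy_points):
        for est in pairwise_ratio_estimates(noisy_points):
            assert est.x_j > est.x_i

    def test_nonpositive_signal_dropped(self):
        pts = [
            GrowthPoint(0, 0, 14, -1.0),
            GrowthPoint(0, 0, 15, 90.0),
            GrowthPoint(0, 0, 16, 160.0),
        ]
        with pytest.warns(UserWarning, match="non-positive"):
            ests = pairwise_ratio_estimates(pts)
        assert len(ests) == 1


class TestPairwiseWeights:
    def test_equal_signals_unit_dx(self):
        pts = [GrowthPoint(0, 0, 14, 50.0), GrowthPoint(0, 0, 15, 50.0)]
        ests = pairwise_ratio_estimates(pts)
        pairwise_sigma_weights(ests, sigma_y=2.4, E_ref=1.85)
        assert ests[0].weight == pytest.approx(50.0**2 / 2.0, rel=1e-12)

    def test_dx_squared_scaling(self):
        p1 = [GrowthPoint(0, 0, 14, 50.0), GrowthPoint(0, 0, 15, 80.0)]
        p2 = [GrowthPoint(0, 0, 14, 50.0), GrowthPoint(0, 0, 16, 80.0)]
        e1 = pairwise_ratio_estimates(p1)
        e2 = pairwise_ratio_estimates(p2)
        pairwise_sigma_weights(e1, 2.4, 1.85)
        pairwise_sigma_weights(e2, 2.4, 1.85)
        assert e2[0].weight == pytest.approx(4 * e1[0].weight, rel=1e-12)

    def test_error_propagation_oracle(self):
        """Finite-difference propagation through Z = ln(E_ij) itself."""
        y_i, y_j, dx, sigma_y, e_ref = 30.0, 120.0, 3, 2.4, 1.8
        pts = [GrowthPoint(0, 0, 14, y_i), GrowthPoint(0, 0, 14 + dx, y_j)]
        ests = pairwise_ratio_estimates(pts)
        pairwise_sigma_weights(ests, sigma_y, e_ref)

        def z_of(yi, yj):
            return (math.log(yj) - math.log(yi)) / dx

        h = 1e-6
        dz_dyi = (z_of(y_i + h, y_j) - z_of(y_i - h, y_j)) / (2 * h)
        dz_dyj = (z_of(y_i, y_j + h) - z_of(y_i, y_j - h)) / (2 * h)
        sigma_z_oracle = math.sqrt((dz_dyi**2 + dz_dyj**2) * sigma_y**2)
        assert ests[0].sigma_Z == pytest.approx(sigma_z_oracle, rel=1e-8)
        assert ests[0].sigma_E == pytest.approx(e_ref * sigma_z_oracle, rel=1e-8)

    def test_weight_symmetry(self):
        a = GrowthPoint(0, 0, 14, 30.0)
        b = GrowthPoint(0, 1, 17, 120.0)
        e1 = pairwise_ratio_estimates([a, b])
        e2 = pairwise_ratio_estimates([b, a])
        pairwise_sigma_weights(e1, 2.4, 1.85)
        pairwise_sigma_weights(e2, 2.4, 1.85)
        assert e1[0].weight == pytest.approx(e2[0].weight, rel=1e-12)
        assert e1[0].E_ij == pytest.approx(e2[0].E_ij, rel=1e-12)


class TestWeightedMean:
    def _mk(self, e_vals, sigma_e):
        ests = []
        for k, (e, s) in enumerate(zip(e_vals, sigma_e)):
            est_pts = [
                GrowthPoint(0, 0, 10, 50.0),
                GrowthPoint(0, 0, 12, 50.0 * e**2),
            ]
            est = pairwise_ratio_estimates(est_pts)[0]
            est.sigma_E = s
            est.weight = 1.0 / s**2
            ests.append(est)
        return ests

    def test_equal_sigmas_reduce_to_unweighted(self):
        ests = self._mk([1.8, 1.85, 1.9], [0.01] * 3)
        s = weighted_mean_pairwise(ests)
        assert s.E_bar_weighted == pytest.approx(s.E_bar_unweighted, rel=1e-12)

    def test_hand_computed_oracle(self):
        # frozen by hand: w = (10000, 2500); Ebar = 1.82; se = sqrt(1/12500)
        ests = self._mk([1.8, 1.9], [0.01, 0.02])
        s = weighted_mean_pairwise(ests)
        assert s.E_bar_weighted == pytest.approx(1.82, rel=1e-12)
        assert s.se_apriori == pytest.approx(0.00894427190999916, rel=1e-10)

    def test_identical_estimates_zero_scatter(self):
        ests = self._mk([1.85, 1.85, 1.85], [0.01, 0.02, 0.03])
        s = weighted_mean_pairwise(ests)
        assert s.chisq == pytest.approx(0.0, abs=1e-20)
        assert s.post_se == pytest.approx(0.0, abs=1e-12)
        assert all(est.norm_resid == pytest.approx(0.0, abs=1e-10) for est in ests)

    def test_single_estimate_error(self):
        ests = self._mk([1.8], [0.01])
        with pytest.raises(DegenerateDesignError):
            weighted_mean_pairwise(ests)


class TestOutlierZone:
    def _estimates(self, e_values):
        pts_sets = []
        ests = []
        for e in e_values:
            pts = [GrowthPoint(0, 0, 10, 50.0), GrowthPoint(0, 0, 12, 50.0 * e**2)]
            est = pairwise_ratio_estimates(pts)[0]
            est.weight = 100.0
            ests.append(est)
        return ests

    def test_flagging_defaults(self):
        ests = self._estimates([1.58, 1.80, 2.20])
        diag = flag_outlier_zone(ests)
        assert [est.flagged for est in ests] == [True, False, True]
        assert diag.n_flagged == 2

    def test_empty(self):
        diag = flag_outlier_zone([])
        assert diag.n_flagged == 0

    def test_weight_diagnostics(self, noisy_points):
        ests, _ = estimate_pairwise(noisy_points, D=2.0)
        diag = flag_outlier_zone(ests, OutlierZone(1.60, 2.15))
        assert diag.max_weight >= diag.max_flagged_weight

    def test_invalid_zone(self):
        with pytest.raises(ValueError):
            OutlierZone(2.0, 1.5)


class TestPairwisePipeline:
    def test_noiseless_exact(self, noiseless_points):
        ests, summary = estimate_pairwise(noiseless_points, D=2.0, sigma_y=2.4)
        assert summary.E_bar_weighted == pytest.approx(1.85, rel=1e-10)
        assert summary.E_bar_unweighted == pytest.approx(1.85, rel=1e-10)
        assert summary.chisq == pytest.approx(0.0, abs=1e-12)
        assert summary.n_pairs == 31
        assert summary.n_excluded_same_cycle == 5

    def test_sigma_default_from_direct_fit(self, noisy_points):
        direct = fit_direct(noisy_points, D=2.0)
        _, s_default = estimate_pairwise(noisy_points, D=2.0)
        _, s_explicit = estimate_pairwise(noisy_points, D=2.0, sigma_y=direct.s_y)
        assert s_default.E_bar_weighted == pytest.approx(
            s_explicit.E_bar_weighted, rel=1e-12
        )


def test_max_disjoint_pairs():
    assert max_disjoint_pairs(9) == 4
    assert max_disjoint_pairs(2) == 1
    assert max_disjoint_pairs(1) == 0
    assert [max_disjoint_pairs(n) for n in range(8)] == [n // 2 for n in range(8)]
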