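import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pairomics.stats import (
    bb_loglik,
    ibb_test,
    missing_value_filter,
    paired_fold_change,
    sgof_adjust,
    shannon_index,
)


def bb_logmass_reference(c, t, pi, phi):
    """Term-by-term log-gamma evaluation, independent of the implementation."""
    if phi == 0:
        return (
            math.lgamma(t + 1) - math.lgamma(c + 1) - math.lgamma(t - c + 1)
            + c * math.log(pi) + (t - c) * math.log(1 - pi)
        )
    a, b = pi / phi, (1 - pi) / phi

    def lbeta(x, y):
        return math.lgamma(x) + math.lgamma(y) - math.lgamma(x + y)

    return (
        math.lgamma(t + 1) - math.lgamma(c + 1) - math.lgamma(t - c + 1)
        + lbeta(c + a, t - c + b) - lbeta(a, b)
    )


class TestBetaBinomialLoglik:
    def test_phi_zero_is_binomial(self):
        for c, t, pi in [(3, 10, 0.3), (0, 5, 0.9), (7, 7, 0.5)]:
            assert bb_loglik([c], [t], [pi], 0.0) == pytest.approx(
                sps.binom.logpmf(c, t, pi), abs=1e-10
            )

    def test_boundary_mass_approaches_one(self):
        assert bb_loglik([5], [5], [1 - 1e-12], 0.0) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("t", [1, 7, 20, 30])
    @pytest.mark.parametrize("pi", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.5])
    def test_mass_sums_to_one(self, t, pi, phi):
        total = sum(
            math.exp(bb_loglik([c], [t], [pi], phi)) for c in range(t + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_term_by_term_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = int(rng.integers(1, 21))
            c = int(rng.integers(0, t + 1))
            pi = float(rng.uniform(0.05, 0.95))
            phi = float(rng.choice([0.0, 0.05, 0.5, 2.0]))
            assert bb_loglik([c], [t], [pi], phi) == pytest.approx(
                bb_logmass_reference(c, t, pi, phi), abs=1e-10
            )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bb_loglik([5], [3], [0.5], 0.1)
        with pytest.raises(ValueError):
            bb_loglik([1], [3], [1.0], 0.1)
        with pytest.raises(ValueError):
            bb_loglik([1], [3], [0.5], -0.1)


class TestIbbTest:
    def test_null_identity(self):
        C = F = np.full(3, 1e4)
        res = ibb_test([50, 60, 40], [50, 60, 40], C, F)
        assert res.r_hat == pytest.approx(1.0, abs=1e-3)
        assert res.lrt == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-3)

    def test_fourfold_example_matches_grid_oracle(self):
        """Counts 4:1 with equal totals recover r ~ 4, agreeing with an
        independent grid-search maximizer."""
        from oracles import grid_search_ml

        c, f = np.array([20, 24, 16]), np.array([5, 6, 4])
        C = F = np.full(3, 1e4)
        res = ibb_test(c, f, C, F)
        assert res.r_hat == pytest.approx(4.0, rel=0.05)
        r_oracle, _ = grid_search_ml(c, f, C, F)
        assert res.r_hat == pytest.approx(r_oracle, rel=1e-3)

    def test_site_swap_inverts_fold(self):
        rng = np.random.default_rng(5)
        c = rng.integers(10, 100, 4)
        f = rng.integers(10, 100, 4)
        C = rng.uniform(5e3, 2e4, 4)
        F = rng.uniform(5e3, 2e4, 4)
        a = ibb_test(c, f, C, F)
        b = ibb_test(f, c, F, C)
        assert a.r_hat == pytest.approx(1.0 / b.r_hat, rel=1e-4)
        assert a.lrt == pytest.approx(b.lrt, abs=1e-8)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-8)

    def test_all_zero_feature_degenerate(self):
        res = ibb_test([0, 0], [0, 0], [100.0, 100.0], [100.0, 100.0])
        assert res.degenerate and res.p_value == 1.0 and res.r_hat == 1.0

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError, match="2 mouse pairs"):
            ibb_test([5], [5], [10.0], [10.0])


class TestSgof:
    def test_all_above_alpha(self):
        res = sgof_adjust([0.2, 0.9, 0.06])
        assert res.R == 0 and res.K == 0 and (res.adjusted_p == 1.0).all()

    def test_exact_binomial_tail_m20(self):
        """With 20 identical tiny p-values the metatest declares 17: the
        18th-ranked adjusted p is the exact Bin(20, 0.05) tail at 3."""
        res = sgof_adjust([0.001] * 20)
        assert res.R == 20 and res.K == 17
        tail_at_3 = sum(
            math.comb(20, j) * 0.05**j * 0.95 ** (20 - j) for j in range(3, 21)
        )
        order = np.argsort(res.adjusted_p)
        assert res.adjusted_p[order][17] == pytest.approx(tail_at_3, abs=1e-12)
        assert tail_at_3 > 0.05

    def test_exact_binomial_tail_m100_mixture(self):
        p = np.concatenate([np.full(10, 1e-4), np.full(90, 0.5)])
        res = sgof_adjust(p)
        assert res.R == 10
        for k in range(1, 11):
            tail = sum(
                math.comb(100, j) * 0.05**j * 0.95 ** (100 - j)
                for j in range(10 - k + 1, 101)
            )
            assert res.adjusted_p[k - 1] == pytest.approx(tail, abs=1e-12)
        expected_K = sum(
            1
            for k in range(1, 11)
            if sum(
                math.comb(100, j) * 0.05**j * 0.95 ** (100 - j)
                for j in range(10 - k + 1, 101)
            )
            <= 0.05
        )
        assert res.K == expected_K

    def test_p_equal_alpha_counts(self):
        res = sgof_adjust([0.05, 0.5])
        assert res.R == 1

    def test_single_test_behaves_like_binomial(self):
        hit = sgof_adjust([0.01])
        assert hit.R == 1 and hit.K == 1 and hit.adjusted_p[0] == pytest.approx(0.05)
        miss = sgof_adjust([0.2])
        assert miss.K == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=50)
    def test_adjusted_monotone_and_K_bounds(self, ps):
        res = sgof_adjust(ps)
        order = np.argsort(np.asarray(ps), kind="stable")
        adj_sorted = res.adjusted_p[order]
        assert np.all(np.diff(adj_sorted) >= -1e-15)
        assert 0 <= res.K <= res.R <= res.m
        stricter = sgof_adjust(ps, gamma=0.01)
        assert stricter.K <= res.K

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            sgof_adjust([0.5, 1.2])


class TestFoldChange:
    C = F = np.full(3, 100.0)

    def test_worked_example(self):
        fc = paired_fold_change([6, 8, 10], [2, 3, 4], self.C, self.F, cf=2.0)
        assert fc.mean_fc_signed == pytest.approx(2.0)
        assert fc.sem == pytest.approx(0.0)
        assert fc.dominant_group == "CC"

    def test_site_swap_antisymmetry_worked(self):
        fc = paired_fold_change([2, 3, 4], [6, 8, 10], self.C, self.F, cf=2.0)
        assert fc.mean_fc_signed == pytest.approx(-2.0)
        assert fc.dominant_group == "F"

    def test_all_equal_no_sign_flip(self):
        fc = paired_fold_change([5, 5, 5], [5, 5, 5], self.C, self.F)
        assert fc.mean_fc_signed == pytest.approx(1.0)

    def test_depth_adjustment(self):
        # raw counts equal, but cecum libraries are twice as deep:
        # depth-adjusted cecum abundance is half the fecal one
        fc = paired_fold_change(
            [40, 40], [40, 40], np.array([200.0, 200.0]), np.array([100.0, 100.0])
        )
        assert fc.mean_fc_signed < -1.2

    @given(
        st.lists(st.integers(1, 500), min_size=3, max_size=3),
        st.lists(st.integers(1, 500), min_size=3, max_size=3),
    )
    @settings(deadline=None, max_examples=100)
    def test_antisymmetry_and_magnitude_properties(self, c, f):
        fc = paired_fold_change(c, f, self.C, self.F)
        rev = paired_fold_change(f, c, self.C, self.F)
        assert abs(fc.mean_fc_signed) >= 1.0
        tied = fc.ratios_cc_over_f.mean() == pytest.approx(
            fc.ratios_f_over_cc.mean(), rel=1e-12
        )
        if not tied:  # at an exact orientation tie no deterministic sign exists
            assert fc.mean_fc_signed == pytest.approx(-rev.mean_fc_signed, rel=1e-10)
            assert fc.sem == pytest.approx(rev.sem, rel=1e-10)

    def test_rejects_bad_cf(self):
        with pytest.raises(ValueError):
            paired_fold_change([1], [1], [10.0], [10.0], cf=0.0)


class TestMissingValueFilter:
    C = F = np.full(3, 100.0)

    @pytest.mark.parametrize("pattern", range(8))
    def test_all_zero_patterns_both_signs(self, pattern):
        """A feature is filtered iff a zero appears in its dominant site,
        exhaustively over all 2^3 zero patterns for each sign."""
        zeros = [(pattern >> i) & 1 for i in range(3)]
        big = np.array([0 if z else 30 for z in zeros])
        small = np.array([1, 2, 1])
        # cecum dominant: zeros in cecum trigger the filter
        fc = paired_fold_change(big, small, self.C, self.F)
        if fc.dominant_group == "CC":
            assert missing_value_filter(big, small, fc) == bool(any(zeros))
        # feces dominant: zeros only in cecum never trigger it
        fc2 = paired_fold_change(small, big, self.C, self.F)
        if fc2.dominant_group == "F":
            assert missing_value_filter(small, big, fc2) == bool(any(zeros))
            zero_in_cecum_only = missing_value_filter(
                np.array([0, 2, 1]), np.array([30, 30, 30]), fc2
            )
            assert zero_in_cecum_only is False


class TestShannon:
    def test_uniform(self):
        assert shannon_index([5, 5, 5, 5]) == pytest.approx(math.log(4), abs=1e-12)

    def test_single_taxon(self):
        assert shannon_index([10, 0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_skewed_example(self):
        assert shannon_index([70, 20, 10]) == pytest.approx(0.80182, abs=1e-5)

    def test_bounded_by_log_richness(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 50, size=30)
        x[0] = 1
        h = shannon_index(x)
        assert 0.0 <= h <= math.log((x > 0).sum()) + 1e-12

    def test_rejects_all_zero(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])
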