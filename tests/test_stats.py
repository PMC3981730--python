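"""Single-case statistics: autocorrelation, SMA, CDC, trend, Wilcoxon, median CI."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from conftest import ar1_series
from fvgame.stats import (DegenerateSeriesError, PhaseSeries,
                          bias_correct_phi, bias_correct_phi_exact, cdc_test,
                          lag1_autocorrelation, median_ci, phase_correlation,
                          slope_trend_test, sma_test, wilcoxon_signed_rank)


class TestLag1Autocorrelation:
    def test_alternating_series(self):
        assert lag1_autocorrelation([1, -1, 1, -1, 1, -1]) == pytest.approx(-5 / 6)

    def test_iid_noise_near_zero(self):
        x = np.random.default_rng(1).standard_normal(1000)
        assert abs(lag1_autocorrelation(x)) < 0.1

    def test_recovers_ar1_coefficient(self):
        x = ar1_series(seed=2, phi=0.8, n=5000)
        assert lag1_autocorrelation(x) == pytest.approx(0.8, abs=0.05)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            lag1_autocorrelation([3.0] * 10)


class TestBiasCorrection:
    def test_one_step_plug_in(self):
        assert bias_correct_phi(0.0, 10) == pytest.approx(0.1)

    def test_correction_vanishes_for_large_n(self):
        assert bias_correct_phi(0.9, 10**7) == pytest.approx(0.9, abs=1e-5)

    def test_clipped_near_unity(self):
        assert bias_correct_phi(0.95, 4) == 0.99

    def test_exact_inversion_is_consistent(self):
        # the exact variant inverts the bias equation: applying the forward
        # bias to its output recovers the input r1
        phi = bias_correct_phi_exact(0.10, 18, n_segments=2)
        r1_back = phi - 2 * (1 + 3 * phi) / 18
        assert r1_back == pytest.approx(0.10, abs=1e-12)


class TestPhaseCorrelation:
    def test_identity_series(self):
        s = PhaseSeries.from_phases([0, 0, 0], [1, 1, 1])
        assert phase_correlation(s) == pytest.approx(1.0)

    def test_point_biserial_example(self):
        s = PhaseSeries.from_phases([1, 2, 3], [4, 5, 6])
        assert phase_correlation(s) == pytest.approx(0.878, abs=1e-3)
        rev = PhaseSeries.from_phases([6, 5, 4], [3, 2, 1])
        assert phase_correlation(rev) == pytest.approx(-0.878, abs=1e-3)

    def test_equals_closed_form_point_biserial(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n0, n1 = rng.integers(3, 10, 2)
            x0, x1 = rng.normal(0, 1, n0), rng.normal(0.5, 1, n1)
            s = PhaseSeries.from_phases(x0, x1)
            x = np.concatenate([x0, x1])
            n = n0 + n1
            # closed form: (m1 - m0) * sqrt(n0 n1) / (n * sd(x))
            expected = (x1.mean() - x0.mean()) * math.sqrt(n0 * n1) / (
                n * x.std(ddof=0))
            assert phase_correlation(s) == pytest.approx(expected, rel=1e-10)

    def test_spearman_matches_scipy(self):
        s = PhaseSeries.from_phases([1.2, 0.4, 0.9], [2.1, 1.7, 3.3, 2.8])
        expected = sps.spearmanr(s.values, s.phase_vector).statistic
        assert phase_correlation(s, kind="spearman") == pytest.approx(expected)

    def test_constant_values_degenerate(self):
        s = PhaseSeries.from_phases([1, 1, 1], [1, 1, 1])
        with pytest.raises(DegenerateSeriesError):
            phase_correlation(s)


class TestSMA:
    def test_perfect_step_gets_minimal_p(self):
        s = PhaseSeries.from_phases([0.0] * 5, [1.0] * 13)
        res = sma_test(s, n_sims=5000, seed=0)
        assert res.r_obs == pytest.approx(1.0)
        assert res.p_value <= 5 / 5001

    def test_deterministic_given_seed(self):
        x = ar1_series(seed=11, phi=0.3, n=18)
        s = PhaseSeries.from_phases(x[:5], x[5:])
        r1 = sma_test(s, n_sims=1000, seed=99)
        r2 = sma_test(s, n_sims=1000, seed=99)
        assert r1 == r2

    def test_power_against_large_shift(self):
        """A +1.5 SD phase shift is detected more often than not.

        Uses the directional test: the analysis predicts the direction of
        the phase change a priori, as intervention studies of this design do.
        """
        hits = 0
        n_runs = 300
        for i in range(n_runs):
            x = ar1_series(seed=5000 + i, phi=0.3, n=18)
            x[5:] += 1.5
            s = PhaseSeries.from_phases(x[:5], x[5:])
            hits += sma_test(s, n_sims=1500, tail="greater",
                             seed=i).p_value < 0.05
        assert hits / n_runs > 0.5

    def test_null_p_values_approximately_uniform(self):
        """Surrogate p-values under a true AR(1) null are near-uniform."""
        pvals = []
        for i in range(500):
            x = ar1_series(seed=20_000 + i, phi=0.3, n=18)
            s = PhaseSeries.from_phases(x[:5], x[5:])
            pvals.append(sma_test(s, n_sims=2000, seed=i).p_value)
        ks = sps.kstest(pvals, "uniform").statistic
        assert ks < 0.08

    def test_spearman_kind_runs(self):
        x = ar1_series(seed=13, phi=0.2, n=18)
        s = PhaseSeries.from_phases(x[:5], x[5:])
        res = sma_test(s, n_sims=500, kind="spearman", seed=1)
        assert 0.0 < res.p_value <= 1.0
        assert res.coefficient_kind == "spearman"


def brute_force_cdc(baseline, treatment, m=0.5):
    """Hand-loop oracle: criteria lines computed point by point."""
    b = np.asarray(baseline, float)
    t = np.asarray(treatment, float)
    sd = b.std(ddof=1)
    mean_line = b.mean() + m * sd
    slope, intercept = np.polyfit(np.arange(1, b.size + 1), b, 1)
    count = 0
    for j, v in enumerate(t):
        idx = b.size + 1 + j
        trend_line = intercept + slope * idx + m * sd
        if v > mean_line and v > trend_line:
            count += 1
    p = sum(math.comb(t.size, k) for k in range(count, t.size + 1)) / 2 ** t.size
    return count, p


class TestCDC:
    def test_hand_computed_example(self):
        res = cdc_test([8, 9, 10, 11, 12], [20] * 5)
        assert res.n_above_both == 5
        assert res.binomial_p == pytest.approx(0.03125)
        assert res.significant

    def test_all_below_baseline_mean(self):
        res = cdc_test([8, 9, 10, 11, 12], [5, 6, 5, 6, 5])
        assert res.n_above_both == 0
        assert res.binomial_p == pytest.approx(1.0)
        assert not res.significant

    def test_significance_threshold_for_13_treatment_days(self):
        # with 13 treatment days, 10 exceedances are needed for p < .05
        b = [10, 10, 10, 10, 10.1]
        for k, expect_sig in [(9, False), (10, True)]:
            t = [20.0] * k + [0.0] * (13 - k)
            res = cdc_test(b, t)
            assert res.n_above_both == k
            assert res.significant is expect_sig
        assert cdc_test(b, [20.0] * 10 + [0.0] * 3).binomial_p == pytest.approx(
            378 / 8192)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            nb = int(rng.integers(5, 12))
            nt = int(rng.integers(5, 15))
            b = rng.normal(0, 1, nb)
            t = rng.normal(rng.uniform(-1, 2), 1, nt)
            res = cdc_test(b, t)
            k, p = brute_force_cdc(b, t)
            assert res.n_above_both == k
            assert res.binomial_p == pytest.approx(p, rel=1e-12)

    def test_degenerate_baseline_flagged(self):
        res = cdc_test([5.0] * 5, [6.0] * 5)
        assert res.degenerate
        assert res.n_above_both == 5

    def test_short_phase_rejected(self):
        with pytest.raises(ValueError):
            cdc_test([1, 2, 3, 4], [5, 6, 7, 8, 9])


class TestSlopeTrend:
    def test_strictly_increasing_is_extreme(self):
        res = slope_trend_test(list(range(10)), n_perm=10_000, seed=0)
        assert res.p_permutation <= 0.001

    def test_null_calibration(self):
        rej = 0
        n_runs = 500
        for i in range(n_runs):
            x = np.random.default_rng(40_000 + i).standard_normal(10)
            rej += slope_trend_test(x, n_perm=2000, seed=i).p_permutation < 0.05
        assert 0.03 <= rej / n_runs <= 0.08

    def test_palindrome_symmetric_under_reversal(self):
        x = [1.0, 3.0, 2.0, 5.0, 2.0, 3.0, 1.0]
        a = slope_trend_test(x, n_perm=1000, seed=7)
        b = slope_trend_test(x[::-1], n_perm=1000, seed=7)
        assert a.p_permutation == b.p_permutation

    def test_constant_series_degenerate(self):
        res = slope_trend_test([2.0] * 8)
        assert res.degenerate
        assert res.p_permutation == 1.0

    def test_runs_test_reported(self):
        res = slope_trend_test(list(range(10)), n_perm=100, seed=1)
        assert 0.0 <= res.runs_p <= 1.0


def enumerate_signed_rank_p(diffs):
    """Full 2^n enumeration of the signed-rank null (independent oracle)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=n)]
    ws = np.asarray(ws)
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


class TestWilcoxon:
    def test_five_identical_positive_shifts(self):
        res = wilcoxon_signed_rank([4, 4, 4, 4, 4], mu0=3)
        assert res.p_value == pytest.approx(0.0625)
        assert res.method == "exact"

    def test_antisymmetric_sample_is_null(self):
        res = wilcoxon_signed_rank([1, 2, 4, 5], mu0=3)
        assert res.p_value == pytest.approx(1.0)

    def test_shifted_parent_sample_significant(self):
        # 35 pre/post differences: most parents one category higher after
        diffs = [1] * 24 + [0] * 8 + [-1] * 3
        res = wilcoxon_signed_rank(diffs, mu0=0)
        assert res.p_value < 0.01

    def test_all_at_null_location_undefined(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([3, 3, 3], mu0=3)

    def test_matches_full_enumeration_up_to_n12(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            # half-integer values create ties among |differences|
            vals = rng.integers(1, 6, n) + rng.choice([0.0, 0.5], n)
            d = vals - 3.0
            if np.all(d == 0):
                continue
            res = wilcoxon_signed_rank(vals, mu0=3.0)
            assert res.p_value == pytest.approx(enumerate_signed_rank_p(d))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            d = rng.permutation(np.arange(1, 11)) * rng.choice([-1, 1], 10)
            res = wilcoxon_signed_rank(d, mu0=0.0)
            expected = sps.wilcoxon(d, alternative="two-sided",
                                    method="exact").pvalue
            assert res.p_value == pytest.approx(expected)

    def test_normal_approximation_for_large_n(self):
        vals = np.r_[np.full(20, 4.0), np.full(10, 2.0)]
        res = wilcoxon_signed_rank(vals, mu0=3.0, exact_max_n=25)
        assert res.method == "normal"
        assert res.p_value < 0.1


class TestMedianCI:
    def test_n7_extreme_rank_pair(self):
        ci = median_ci([1, 2, 3, 4, 5, 6, 7])
        assert ci.rank == 1
        assert (ci.lower, ci.upper) == (1, 7)
        assert ci.achieved_coverage == pytest.approx(1 - 2 / 128)

    def test_teacher_item_rule(self):
        ci = median_ci([4, 4, 5, 5, 5, 5, 5])
        assert (ci.lower, ci.upper) == (4, 5)
        assert ci.lower > 3  # judged significantly above the neutral rating

    def test_identical_values_collapse(self):
        ci = median_ci([4] * 8)
        assert ci.lower == ci.upper == 4

    def test_too_small_sample_flagged(self):
        ci = median_ci([1, 2, 3, 4, 5])
        assert not ci.computable
        assert ci.lower is None

    def test_coverage_at_least_level_when_computable(self):
        for n in range(6, 30):
            ci = median_ci(list(range(n)))
            assert ci.computable
            assert ci.achieved_coverage >= 0.95
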