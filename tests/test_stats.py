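import numpy as np
import pytest
from scipy.special import expit, logit

from pesival.stats import (
    LogisticFit,
    auroc_correlation,
    binomial_ci,
    calibration_table,
    compare_auroc_paired,
    fit_logistic,
    group_compare,
    paired_auroc_test,
    roc_auc,
)

from _oracles import brute_force_auc, delong_paired_test


class TestLogistic:
    def test_null_slope_near_zero(self, rng):
        scores = rng.standard_normal(2000)
        died = rng.uniform(size=2000) < 0.3
        fit = fit_logistic(scores, died)
        assert fit.converged
        # slope SE under the null is ~1/sqrt(n p (1-p)) ~= 0.049
        assert abs(fit.slope) < 3 * 0.049

    def test_binary_predictor_recovers_log_odds_ratio(self):
        """With a binary score the MLE slope equals the 2x2-table log
        odds ratio exactly; here the odds ratio is 2."""
        scores = [0] * 500 + [1] * 600
        died = [True] * 100 + [False] * 400 + [True] * 200 + [False] * 400
        fit = fit_logistic(scores, died)
        assert fit.converged
        assert fit.slope == pytest.approx(np.log(2.0), abs=1e-5)
        assert fit.intercept == pytest.approx(np.log(100 / 400), abs=1e-5)

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic([3.0] * 10, [True] * 5 + [False] * 5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic([1.0, 2.0, 3.0], [False, False, False])

    def test_complete_separation_flagged_not_raised(self):
        fit = fit_logistic(
            [0.0, 1.0, 2.0, 10.0, 11.0, 12.0],
            [False, False, False, True, True, True],
        )
        assert not fit.converged


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11], [False, False, False, True, True])
        assert res.auc == 1.0

    def test_all_ties_give_half(self):
        res = roc_auc([5.0] * 10, [True] * 4 + [False] * 6)
        assert res.auc == 0.5

    def test_matches_brute_force_on_random_instances(self, rng):
        """Midrank AUROC equals the exhaustive pairwise concordance
        oracle for every random instance up to n = 50."""
        for trial in range(30):
            n = int(rng.integers(4, 51))
            scores = rng.integers(0, 8, size=n).astype(float)  # many ties
            died = rng.uniform(size=n) < 0.4
            if died.all() or not died.any():
                continue
            assert roc_auc(scores, died).auc == pytest.approx(
                brute_force_auc(scores, died), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(200)
        died = rng.uniform(size=200) < 0.3
        a = roc_auc(scores, died)
        b = roc_auc(np.exp(scores), died)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])

    def test_hanley_mcneil_se_formula(self):
        res = roc_auc([1, 2, 3, 4, 10, 11], [False] * 4 + [True] * 2)
        a = res.auc
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        expected = np.sqrt(
            (a * (1 - a) + (2 - 1) * (q1 - a * a) + (4 - 1) * (q2 - a * a)) / 8
        )
        assert res.se == pytest.approx(expected, abs=1e-12)


class TestAurocCorrelationGrid:
    def test_zero_correlation_maps_to_zero(self):
        assert auroc_correlation(0.0, 0.8) == pytest.approx(0.0, abs=1e-9)

    def test_identical_scores_map_to_one(self):
        assert auroc_correlation(1.0, 0.75) == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_at_half_area(self):
        # at A = 0.5 the binormal model gives r = asin(rho/2)/asin(1/2)
        rho = 0.5
        expected = np.arcsin(rho / 2) / np.arcsin(0.5)
        assert auroc_correlation(rho, 0.5) == pytest.approx(expected, abs=5e-3)

    def test_monotone_in_correlation(self):
        values = [auroc_correlation(r, 0.8) for r in np.linspace(0, 1, 11)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))


class TestPairedComparison:
    def test_score_compared_with_itself(self, rng):
        scores = rng.standard_normal(100)
        died = rng.uniform(size=100) < 0.4
        cmp = paired_auroc_test(scores, scores, died)
        assert cmp.delta == 0.0 and cmp.z == 0.0 and cmp.p_value == 1.0

    def test_antisymmetric_under_swap(self, rng):
        a = rng.standard_normal(150)
        b = a + rng.standard_normal(150)
        died = rng.uniform(size=150) < 0.35
        ab = paired_auroc_test(a, b, died)
        ba = paired_auroc_test(b, a, died)
        assert ab.z == pytest.approx(-ba.z, abs=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)

    def test_reduces_to_unpaired_z_when_r_zero(self):
        a = roc_auc([1, 2, 3, 4, 3.5, 8], [False] * 4 + [True] * 2)
        b = roc_auc([1, 3, 2, 4, 5, 2.5], [False] * 4 + [True] * 2)
        cmp = compare_auroc_paired(a, b, 0.0, 0.0)
        assert cmp.r == pytest.approx(0.0, abs=1e-9)
        assert cmp.z == pytest.approx(
            (a.auc - b.auc) / np.sqrt(a.se**2 + b.se**2), abs=1e-9
        )

    def test_mismatched_groups_rejected(self):
        a = roc_auc([1, 2, 3, 4], [False, False, True, True])
        b = roc_auc([1, 2, 3, 4, 5], [False, False, False, True, True])
        with pytest.raises(ValueError):
            compare_auroc_paired(a, b, 0.5, 0.5)

    def test_decisions_agree_with_delong_oracle(self):
        """On simulated paired scores (n = 500) the accept/reject decision
        at alpha = 0.05 matches an independent DeLong implementation."""
        agreements = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = 500
            latent = rng.standard_normal(n)
            died = rng.uniform(size=n) < expit(-1.5 + 1.2 * latent)
            if died.sum() < 10 or died.sum() > n - 10:
                continue
            shift = rng.uniform(0.0, 0.8)
            a = latent + rng.standard_normal(n)
            b = (1 - shift) * latent + rng.standard_normal(n)
            ours = paired_auroc_test(a, b, died)
            _, _, _, p_oracle = delong_paired_test(a, b, died)
            assert (ours.p_value < 0.05) == (p_oracle < 0.05), (
                seed, ours.p_value, p_oracle
            )
            # the p-values themselves should be close, not just the decisions
            assert ours.p_value == pytest.approx(p_oracle, abs=0.05)
            agreements += 1
        assert agreements >= 15


class TestCalibration:
    def test_constant_prediction_fills_every_bin(self, rng):
        fit = LogisticFit(intercept=logit(0.3), slope=0.0, converged=True, n=100)
        scores = rng.standard_normal(100)
        died = rng.uniform(size=100) < 0.3
        table = calibration_table(fit, scores, died, binning="deciles")
        for b in table.bins:
            assert b.predicted == pytest.approx(0.3, abs=1e-12)

    def test_distinct_values_mode_bins_by_value(self, rng):
        scores = np.repeat([0, 1, 2, 3, 4, 5], 30).astype(float)
        died = rng.uniform(size=scores.size) < expit(-2 + 0.5 * scores)
        fit = fit_logistic(scores, died)
        table = calibration_table(fit, scores, died, binning="distinct-values")
        assert len(table.bins) == 6
        assert table.total_n == scores.size

    def test_decile_bins_partition_cohort(self, rng):
        scores = rng.standard_normal(500)
        died = rng.uniform(size=500) < expit(-1 + scores)
        fit = fit_logistic(scores, died)
        table = calibration_table(fit, scores, died, binning="deciles")
        assert len(table.bins) == 10
        assert table.total_n == 500

    def test_well_specified_model_calibrates(self):
        """Large-sample self-consistency: per-bin observed mortality within
        3 binomial SEs of the mean predicted probability."""
        rng = np.random.default_rng(99)
        scores = rng.standard_normal(6000)
        died = rng.uniform(size=6000) < expit(-1.0 + 0.8 * scores)
        fit = fit_logistic(scores, died)
        table = calibration_table(fit, scores, died, binning="deciles")
        for b in table.bins:
            se = np.sqrt(max(b.predicted * (1 - b.predicted), 1e-9) / b.n)
            assert abs(b.observed - b.predicted) <= 3 * se + 1e-9

    def test_unconverged_fit_rejected(self):
        fit = LogisticFit(np.nan, np.nan, converged=False, n=10)
        with pytest.raises(ValueError):
            calibration_table(fit, [1.0, 2.0], [True, False])


class TestBinomialCi:
    def test_zero_events_gives_zero_proportion_and_lower(self):
        p, lo, _ = binomial_ci(0, 10)
        assert (p, lo) == (0.0, 0.0)

    def test_lower_bound_truncated_at_zero(self):
        # p=0.01: untruncated Wald lower bound would be negative
        _, lo, _ = binomial_ci(1, 100)
        assert lo == 0.0

    def test_width_shrinks_like_root_n(self):
        _, lo1, hi1 = binomial_ci(30, 100)
        _, lo4, hi4 = binomial_ci(120, 400)
        assert (hi4 - lo4) == pytest.approx((hi1 - lo1) / 2.0, rel=1e-9)

    def test_wilson_narrower_near_boundary(self):
        _, lo_wald, _ = binomial_ci(1, 20, method="wald")
        _, lo_wilson, _ = binomial_ci(1, 20, method="wilson")
        assert lo_wilson > lo_wald  # wilson does not truncate at 0 here

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 4)
        with pytest.raises(ValueError):
            binomial_ci(-1, 4)
        with pytest.raises(ValueError):
            binomial_ci(1, 4, method="jeffreys")


class TestGroupCompare:
    def test_large_2x2_uses_chi_square(self):
        # cancer history by survival: 45/150 non-survivors, 140/662 survivors
        non_survivors = [1] * 45 + [0] * 105
        survivors = [1] * 140 + [0] * 522
        result = group_compare(non_survivors, survivors, kind="categorical")
        assert result.test == "chi-square"
        assert result.p_value == pytest.approx(0.026, abs=0.0005)

    def test_identical_proportions_give_p_one(self):
        group = [1] * 20 + [0] * 30
        result = group_compare(group, list(group), kind="categorical")
        assert result.test == "chi-square"
        assert result.p_value == pytest.approx(1.0)

    def test_small_expected_count_switches_to_fisher(self):
        result = group_compare([1, 1, 0, 0, 0], [0, 0, 0, 0, 0, 1], kind="categorical")
        assert result.test == "fisher"

    def test_normal_groups_use_t_test(self, rng):
        a = rng.normal(0, 1, 80)
        b = rng.normal(0.2, 1, 80)
        assert group_compare(a, b, kind="continuous").test == "t-test"

    def test_skewed_groups_use_mann_whitney(self, rng):
        a = rng.lognormal(0, 1.5, 80)
        b = rng.lognormal(0.3, 1.5, 80)
        assert group_compare(a, b, kind="continuous").test == "mann-whitney"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0], kind="continuous")
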