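"""Accuracy, selection differentials, report aggregation, conversions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orchardgs import evalsel
from orchardgs.examples import (ACCURACY_GRID, APPLICATION_FAMILY_SIZES,
                                EXAMPLE_PI, N_EXTRA_PANEL_SNPS, N_ROBUST_SNPS,
                                accuracy_long)


class TestAccuracy:
    def test_perfect_correlation(self):
        x = np.arange(10, dtype=float)
        rec = evalsel.accuracy(x, x)
        assert rec.pearson_r == pytest.approx(1.0)
        assert rec.ci_high == pytest.approx(1.0)

    def test_fisher_ci_closed_form(self):
        """r = 0, n = 103: the 95% CI is +/- tanh(1.96/10), length 0.3871."""
        lo, hi = evalsel.fisher_ci(0.0, 103)
        assert hi == pytest.approx(0.19354, abs=2e-4)
        assert hi - lo == pytest.approx(0.3871, abs=3e-4)
        assert lo == -hi

    def test_ci_shrinks_with_family_size(self):
        lengths = []
        for n in (109, 178, 269, 662):
            lo, hi = evalsel.fisher_ci(0.2, n)
            lengths.append(hi - lo)
        assert all(a > b for a, b in zip(lengths, lengths[1:]))

    def test_zero_variance_returns_reason(self):
        rec = evalsel.accuracy(np.ones(10), np.arange(10.0))
        assert rec.pearson_r is None
        assert rec.reason == "zero variance"

    def test_spearman_added_when_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        rec = evalsel.accuracy(x, y, skew_flag=True)
        assert rec.spearman_rho is not None

    def test_ci_coverage(self):
        """Monte-Carlo coverage of the Fisher-z 95% CI at rho = 0.3,
        n = 662: between 93% and 97% over 2000 replicates."""
        rng = np.random.default_rng(42)
        n, rho, reps = 662, 0.3, 2000
        cover = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            r = np.corrcoef(x, y)[0, 1]
            lo, hi = evalsel.fisher_ci(r, n)
            cover += lo <= rho <= hi
        assert 0.93 <= cover / reps <= 0.97


class TestSkewness:
    def test_symmetric_scores_not_flagged(self):
        scores = np.repeat([1, 2, 3, 4, 5], 10)
        assert not evalsel.skewness_flag(scores)

    def test_defect_trait_distribution_flagged(self):
        scores = np.array([1] * 95 + [2, 3, 4, 5, 5])
        assert evalsel.skewness_flag(scores)

    def test_constant_flagged_with_warning(self):
        with pytest.warns(UserWarning):
            assert evalsel.skewness_flag(np.ones(20))

    def test_matches_moment_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(size=200)
        m = x.mean()
        n = x.size
        m2 = np.mean((x - m) ** 2)
        m3 = np.mean((x - m) ** 3)
        g1 = m3 / m2**1.5
        expected = g1 * np.sqrt(n * (n - 1)) / (n - 2)  # bias-corrected
        assert stats.skew(x, bias=False) == pytest.approx(expected)
        assert evalsel.skewness_flag(x) == (abs(expected) > 1)


class TestSelectionDifferential:
    def test_exact_arithmetic(self):
        """phenotype == GBV, k=2, values 1..4: top mean 3.5, bottom 1.5."""
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        sd = evalsel.selection_differential(vals, vals, k=2)
        assert sd.diff_top_minus_bottom == pytest.approx(2.0)

    def test_low_direction_sign(self):
        """For defect traits low scores win: a model whose low-GBV tail has
        low phenotypes gets a positive (favourable) differential."""
        g = np.arange(20.0)
        y = np.arange(20.0)
        sd = evalsel.selection_differential(g, y, k=5, direction="low")
        assert sd.diff_top_minus_bottom > 0

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            evalsel.selection_differential(np.arange(10.0), np.arange(10.0), k=6)

    def test_permutation_null_calibration(self):
        """Independent GBV: differentials centred on 0 and Welch p-values
        with ~5% type-I error at alpha = 0.05 (2000 permutations)."""
        rng = np.random.default_rng(8)
        n, k, reps = 662, 50, 2000
        y = rng.integers(1, 6, n).astype(float)
        diffs = np.empty(reps)
        pvals = np.empty(reps)
        for i in range(reps):
            g = rng.permutation(n).astype(float)
            sd = evalsel.selection_differential(g, y, k=k)
            diffs[i] = sd.diff_top_minus_bottom
            pvals[i] = sd.p_value
        assert abs(diffs.mean()) < 0.05
        assert (pvals < 0.05).mean() == pytest.approx(0.05, abs=0.02)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_power_with_accurate_gbv(self):
        """h2 = 0.6 and GBV = TBV: the differential is significant at the
        1% level in >= 9/10 replicates."""
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(300 + rep)
            n = 662
            tbv = rng.normal(0, np.sqrt(0.6), n)
            y = tbv + rng.normal(0, np.sqrt(0.4), n)
            sd = evalsel.selection_differential(tbv, y, k=50)
            hits += (sd.p_value < 0.01) and (sd.diff_top_minus_bottom > 0)
        assert hits >= 9


class TestAggregateReport:
    def test_family_means_from_example_grid(self):
        """Published-style grid: the four-trait mean for the largest family
        and the all-trait mean for the third family both come to 0.18."""
        rep = evalsel.aggregate_report(accuracy_long())
        assert rep["mean_symmetric_traits"]["AF1_Da66"] == pytest.approx(0.18, abs=0.005)
        assert rep["mean_all_traits"]["AF3_31Fu"] == pytest.approx(0.18, abs=0.005)

    def test_trait_mean_and_max(self):
        rep = evalsel.aggregate_report(accuracy_long())
        assert rep["trait_means"]["attractiveness"] == pytest.approx(0.21, abs=0.005)
        assert rep["max_accuracy"] == pytest.approx(0.5)

    def test_families_missing_a_trait_use_available_cells(self):
        rep = evalsel.aggregate_report(accuracy_long())
        assert rep["n_cells"]["AF1_Da66"] == 9  # no pre-harvest dropping
        assert rep["n_cells"]["AF3_31Fu"] == 10

    def test_constant_grid(self):
        df = pd.DataFrame({"family": ["f1", "f1", "f2", "f2"],
                           "trait": ["a", "b", "a", "b"],
                           "r": [0.3] * 4})
        rep = evalsel.aggregate_report(df, symmetric_traits=("a",))
        assert (rep["mean_all_traits"] == 0.3).all()
        assert (rep["trait_means"] == 0.3).all()
        assert rep["max_accuracy"] == 0.3


class TestRelatednessAccuracy:
    def test_identity_and_antiorder(self):
        rel = pd.DataFrame({"top10": [0.1, 0.2, 0.3, 0.4]},
                           index=list("abcd"))
        acc = pd.DataFrame({"t": [0.1, 0.2, 0.3, 0.4]}, index=list("abcd"))
        out = evalsel.relatedness_accuracy_correlation(rel, acc)
        assert out.loc["t", "top10"] == pytest.approx(1.0)
        acc2 = pd.DataFrame({"t": [0.4, 0.3, 0.2, 0.1]}, index=list("abcd"))
        out2 = evalsel.relatedness_accuracy_correlation(rel, acc2)
        assert out2.loc["t", "top10"] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        rel = pd.DataFrame({"m": x}, index=list("abcde"))
        acc = pd.DataFrame({"t": y}, index=list("abcde"))
        out = evalsel.relatedness_accuracy_correlation(rel, acc)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle = cov / (x.std() * y.std())
        assert out.loc["t", "m"] == pytest.approx(oracle)

    def test_too_few_families_rejected(self):
        rel = pd.DataFrame({"m": [0.1, 0.2]}, index=["a", "b"])
        acc = pd.DataFrame({"t": [0.1, 0.2]}, index=["a", "b"])
        with pytest.raises(ValueError):
            evalsel.relatedness_accuracy_correlation(rel, acc)


class TestRegressionAndConversion:
    def test_slope_one_when_accuracy_is_sqrt_h2(self):
        h2 = np.array([0.1, 0.3, 0.6])
        assert evalsel.accuracy_h2_regression(np.sqrt(h2), h2) == pytest.approx(1.0)

    def test_slope_half(self):
        h2 = np.array([0.2, 0.5])
        assert evalsel.accuracy_h2_regression(0.5 * np.sqrt(h2), h2) \
            == pytest.approx(0.5)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(1)
        h2 = rng.uniform(0.05, 0.7, 10)
        acc = rng.uniform(-0.2, 0.6, 10)
        x = np.sqrt(h2)
        assert evalsel.accuracy_h2_regression(acc, h2) \
            == pytest.approx(np.sum(x * acc) / np.sum(x * x))

    def test_pi_to_nqtl(self):
        p = N_ROBUST_SNPS + N_EXTRA_PANEL_SNPS
        assert p == 7829
        assert evalsel.pi_to_nqtl(EXAMPLE_PI["over_colour"], p) == 55
        assert evalsel.pi_to_nqtl(0.0, p) == 0
        assert evalsel.pi_to_nqtl(1.0, p) == p

    def test_selected_fraction_of_largest_family(self):
        assert 50 / APPLICATION_FAMILY_SIZES["AF1_Da66"] \
            == pytest.approx(0.075, abs=0.001)


class TestAppendixIdentity:
    def test_perfect_gbv_quarter_heritability(self):
        """ghat = TBV and h2 = 0.25: accuracy against phenotype is
        sqrt(0.25) = 0.5."""
        rng = np.random.default_rng(11)
        tbv = rng.normal(size=5000)
        out = evalsel.appendix_accuracy_decomposition(tbv, tbv, 0.25, rng)
        assert out["cor_gbv_pheno"] == pytest.approx(0.5, abs=0.03)

    def test_h2_one_sides_equal(self):
        rng = np.random.default_rng(12)
        tbv = rng.normal(size=1000)
        g = tbv + rng.normal(0, 0.5, 1000)
        out = evalsel.appendix_accuracy_decomposition(g, tbv, 1.0, rng)
        assert out["difference"] == pytest.approx(0.0, abs=1e-12)

    def test_independent_gbv_both_sides_zero(self):
        rng = np.random.default_rng(13)
        tbv = rng.normal(size=5000)
        g = rng.normal(size=5000)
        out = evalsel.appendix_accuracy_decomposition(g, tbv, 0.5, rng)
        assert abs(out["cor_gbv_pheno"]) < 0.05
        assert abs(out["cor_gbv_tbv_scaled"]) < 0.05

    @pytest.mark.parametrize("h2", [0.1, 0.3, 0.6])
    def test_identity_across_heritabilities(self, h2):
        """cor(ghat, y) tracks cor(ghat, TBV) * sqrt(h2) within 0.03 at
        n = 5000 for an imperfect predictor."""
        rng = np.random.default_rng(int(h2 * 100))
        tbv = rng.normal(size=5000)
        g = 0.8 * tbv + rng.normal(0, 0.6, 5000)
        out = evalsel.appendix_accuracy_decomposition(g, tbv, h2, rng)
        assert abs(out["difference"]) <= 0.03
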