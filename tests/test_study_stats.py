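import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import hpwave as hw
from hpwave.study_stats import DesignParameters, binomial_critical_value


class TestWelch:
    def test_identical_groups_null(self):
        t, df, p = hw.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_swap_antisymmetry(self):
        a, b = [1.0, 2.0, 5.0], [2.0, 4.0, 4.5, 8.0]
        t1, df1, p1 = hw.welch_t_test(a, b)
        t2, df2, p2 = hw.welch_t_test(b, a)
        assert t1 == pytest.approx(-t2) and df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_closed_form_oracle(self):
        """Recompute t, Welch-Satterthwaite df and p from the definitions."""
        a, b = np.array([1.0, 2, 3, 4]), np.array([3.0, 4, 5, 6])
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t_ref = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_ref = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        p_ref = 2 * sps.t.sf(abs(t_ref), df_ref)
        t, df, p = hw.welch_t_test(a, b)
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert df == pytest.approx(df_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            hw.welch_t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            hw.welch_t_test([2.0, 2.0], [3.0, 3.0])

    def test_null_p_values_uniform(self):
        """KS statistic of 2000 null replicates below the 1% critical value."""
        rng = np.random.default_rng(12)
        a = rng.standard_normal((2000, 10))
        b = rng.standard_normal((2000, 10))
        res = sps.ttest_ind(a, b, axis=1, equal_var=False)
        ks = sps.kstest(res.pvalue, "uniform").statistic
        assert ks < 1.63 / math.sqrt(2000)


class TestRocAuc:
    def test_perfect_separation(self):
        curve, auc = hw.roc_auc([0.1, 0.2, 0.8, 0.9], ["NF", "NF", "WF", "WF"])
        assert auc == 1.0
        assert {"threshold", "fpr", "tpr"} <= set(curve.columns)

    def test_permutation_null(self):
        rng = np.random.default_rng(7)
        scores = rng.standard_normal(2000)
        labels = np.where(rng.uniform(size=2000) < 0.5, "WF", "NF")
        _, auc = hw.roc_auc(scores, labels)
        n1 = int(np.sum(labels == "WF"))
        n0 = 2000 - n1
        se = math.sqrt((n0 + n1 + 1) / (12 * n0 * n1))
        assert abs(auc - 0.5) < 3 * se

    @settings(derandomize=True, max_examples=120)
    @given(
        scores=st.lists(st.integers(0, 5), min_size=4, max_size=50),
        labels=st.lists(st.booleans(), min_size=4, max_size=50),
    )
    def test_auc_equals_mann_whitney_pair_count(self, scores, labels):
        n = min(len(scores), len(labels))
        scores, labels = scores[:n], labels[:n]
        if not (any(labels) and not all(labels)):
            return
        lab = ["WF" if l else "NF" for l in labels]
        _, auc = hw.roc_auc(scores, lab)
        pos = [s for s, l in zip(scores, labels) if l]
        neg = [s for s, l in zip(scores, labels) if not l]
        pairs = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            hw.roc_auc([1, 2], ["WF", "WF"])


class TestPerformance:
    def test_perfect_predictions(self):
        truth = ["WF"] * 5 + ["NF"] * 5
        r = hw.performance(truth, truth)
        assert (r.tp, r.fp, r.tn, r.fn) == (5, 0, 5, 0)
        assert r.sensitivity == r.specificity == 1.0
        assert r.ci_sensitivity[1] == 1.0 and r.ci_specificity[1] == 1.0

    def test_clopper_pearson_oracle(self):
        """8/10 detected: interval from independent beta-quantile evaluation."""
        preds = ["WF"] * 8 + ["NF"] * 2
        truth = ["WF"] * 10
        r = hw.performance(preds, truth)
        assert r.sensitivity == pytest.approx(0.8)
        lo = sps.beta.ppf(0.025, 8, 3)
        hi = sps.beta.ppf(0.975, 9, 2)
        assert r.ci_sensitivity[0] == pytest.approx(lo, abs=1e-9)
        assert r.ci_sensitivity[1] == pytest.approx(hi, abs=1e-9)
        assert r.ci_sensitivity == pytest.approx((0.444, 0.975), abs=5e-4)

    def test_all_nf_predictions(self):
        preds = ["NF"] * 10
        truth = ["WF"] * 4 + ["NF"] * 6
        r = hw.performance(preds, truth)
        assert r.sensitivity == 0.0 and r.specificity == 1.0

    def test_density_strata(self):
        preds = ["WF", "NF", "WF", "NF"]
        truth = ["WF", "WF", "NF", "NF"]
        strata = ["B", "B", "C", "C"]
        r = hw.performance(preds, truth, strata=strata)
        assert set(r.strata) == {"B", "C"}
        assert r.strata["B"].sensitivity == 0.5
        assert r.strata["C"].specificity == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hw.performance(["WF"], ["WF", "NF"])

    def test_empty_positive_class_flagged(self):
        r = hw.performance(["NF", "NF"], ["NF", "NF"])
        assert math.isnan(r.sensitivity) and r.specificity == 1.0

    def test_clopper_pearson_coverage(self):
        """Exact intervals reach nominal coverage at n = 175."""
        rng = np.random.default_rng(3)
        from statsmodels.stats.proportion import proportion_confint

        n = 175
        for p in (0.6, 0.7, 0.9):
            k = rng.binomial(n, p, size=1000)
            lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
            coverage = np.mean((lo <= p) & (p <= hi))
            se = math.sqrt(0.95 * 0.05 / 1000)
            assert coverage >= 0.95 - 3 * se


class TestBinomialDesign:
    def test_single_trial_case(self):
        assert binomial_critical_value(1, 0.5, 0.6) == 1

    def test_ten_trial_tail_enumeration(self):
        # P(X >= 9) = 11/1024 <= 0.05 < P(X >= 8) = 56/1024
        assert binomial_critical_value(10, 0.5, 0.05) == 9
        assert sps.binom.sf(8, 10, 0.5) == pytest.approx(11 / 1024)

    def test_critical_value_monotone_in_alpha(self):
        ks = [binomial_critical_value(50, 0.6, a) for a in (0.01, 0.05, 0.1, 0.3)]
        assert ks == sorted(ks, reverse=True)

    @pytest.mark.parametrize("n", [50, 175, 400])
    def test_exact_size_bounded_by_alpha(self, n):
        k = binomial_critical_value(n, 0.60, 0.05)
        assert sps.binom.sf(k - 1, n, 0.60) <= 0.05
        assert sps.binom.sf(k - 2, n, 0.60) > 0.05  # smallest such k

    def test_power_limits_and_monotonicity(self):
        d = DesignParameters()
        assert hw.power_at_n(175, DesignParameters(p1=0.999)) == pytest.approx(1.0, abs=1e-6)
        powers = [hw.power_at_n(n, d) for n in range(150, 400, 25)]
        assert all(b >= a - 0.02 for a, b in zip(powers, powers[1:]))
        p_grid = [hw.power_at_n(175, DesignParameters(p1=p)) for p in (0.65, 0.70, 0.80)]
        assert p_grid == sorted(p_grid)

    def test_power_matches_monte_carlo(self):
        d = DesignParameters()
        exact = hw.power_at_n(175, d)
        k = binomial_critical_value(175, d.p0, d.alpha)
        rng = np.random.default_rng(8)
        draws = rng.binomial(175, d.p1, size=100_000)
        mc = np.mean(draws >= k)
        se = math.sqrt(exact * (1 - exact) / 100_000)
        assert abs(mc - exact) < 3 * se

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            DesignParameters(p0=0.7, p1=0.6)

    def test_required_n_is_minimal(self):
        d = DesignParameters()
        n_lesion, n_total = hw.required_n(d)
        assert hw.power_at_n(n_lesion, d) >= d.power_target
        assert hw.power_at_n(n_lesion - 1, d) < d.power_target
        # brute-force scan oracle
        scan = next(n for n in range(1, 1000) if hw.power_at_n(n, d) >= d.power_target)
        assert n_lesion == scan
        assert n_total == math.ceil(n_lesion / d.prevalence)

    def test_total_enrollment_arithmetic(self):
        assert hw.total_enrollment(175, 0.5) == 350
        assert hw.total_enrollment(10, 1.0) == 10
        with pytest.raises(ValueError):
            hw.total_enrollment(10, 0.0)
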