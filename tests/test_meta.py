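import numpy as np
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from kappameta import (
    CrossTab,
    EmptyStudyError,
    InsufficientPeriodsError,
    PeriodEstimate,
    QUIS_SCALE,
    ZeroVarianceError,
    analyze_study,
    averaged,
    collapse_tables,
    dl_tau2,
    fixed_effect,
    heterogeneity,
    kappa_se,
    named_scheme,
    random_effect,
    weighted_kappa,
)
from kappameta.simulate import SimConfig, simulate_study


def two_periods(k1=0.5, k2=0.7, v1=0.01, v2=0.01):
    return [PeriodEstimate("p1", k1, v1), PeriodEstimate("p2", k2, v2)]


def random_estimates(rng, g=None):
    g = g or int(rng.integers(3, 12))
    return [
        PeriodEstimate(f"p{i}", float(rng.normal(0.5, 0.2)),
                       float(rng.uniform(0.003, 0.05)))
        for i in range(g)
    ]


class TestCollapse:
    def test_cellwise_sum_of_published_periods(self, lowest_tab, highest_tab):
        tab = collapse_tables([lowest_tab, highest_tab])
        assert tab.counts[1, 1] == 9 + 11
        assert tab.n == 44
        assert np.array_equal(tab.counts,
                              lowest_tab.counts + highest_tab.counts)

    def test_single_table_is_itself(self, collapsed_tab):
        tab = collapse_tables([collapsed_tab])
        assert np.array_equal(tab.counts, collapsed_tab.counts)

    def test_scale_mismatch(self, collapsed_tab):
        from kappameta import CategoryScale

        other = CrossTab(CategoryScale(("a", "b")), np.eye(2, dtype=int))
        with pytest.raises(ValueError, match="scale"):
            collapse_tables([collapsed_tab, other])

    def test_copies_leave_kappa_and_shrink_se(self, collapsed_tab):
        """Collapsing c identical tables keeps kappa, divides SE by sqrt(c)."""
        W = named_scheme("A4")
        base = weighted_kappa(collapsed_tab, W)
        for c in (2, 5):
            stacked = collapse_tables([collapsed_tab] * c)
            est = weighted_kappa(stacked, W)
            assert est.kappa == pytest.approx(base.kappa, abs=1e-14)
            assert est.se == pytest.approx(base.se / np.sqrt(c), abs=1e-14)


class TestFixedEffect:
    def test_equal_weights_give_arithmetic_mean(self):
        res = fixed_effect(two_periods())
        assert res.estimate == pytest.approx(0.6, abs=1e-14)
        assert res.se == pytest.approx(np.sqrt(1 / 200), abs=1e-14)

    def test_repeated_value_recovered(self):
        ests = [PeriodEstimate(f"p{i}", 0.42, 0.01 * (i + 1)) for i in range(5)]
        assert fixed_effect(ests).estimate == pytest.approx(0.42, abs=1e-14)

    def test_weights_sum_to_100_percent(self):
        rng = np.random.default_rng(1)
        res = fixed_effect(random_estimates(rng))
        assert sum(res.meta_weights.values()) == pytest.approx(100.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError, match="p2"):
            fixed_effect(two_periods(v2=0.0))

    def test_single_period_rejected(self):
        with pytest.raises(InsufficientPeriodsError):
            fixed_effect([PeriodEstimate("p1", 0.5, 0.01)])


class TestHeterogeneity:
    def test_identical_estimates_give_zero(self):
        ests = [PeriodEstimate(f"p{i}", 0.5, 0.01) for i in range(4)]
        chi2, df, p = heterogeneity(ests)
        assert chi2 == pytest.approx(0.0, abs=1e-20)
        assert df == 3 and p == pytest.approx(1.0)

    def test_hand_example(self):
        chi2, df, p = heterogeneity(two_periods())
        assert chi2 == pytest.approx(2.0, abs=1e-12)
        assert df == 1

    def test_rejection_rule_matches_095_percentile(self):
        """With g=18 periods the 5% heterogeneity cut-point is 27.59."""
        from scipy import stats

        cut = stats.chi2.ppf(0.95, 17)
        assert cut == pytest.approx(27.59, abs=0.01)
        ests = [PeriodEstimate(f"p{i}", 0.5, 0.01) for i in range(17)]
        ests.append(PeriodEstimate("p17", 0.5 + np.sqrt(0.01 * 28.0), 0.01))
        chi2, df, p = heterogeneity(ests)
        assert df == 17
        assert (p < 0.05) == (chi2 > cut)


class TestDLTau2:
    def test_hand_example(self):
        # chi2=2, g-1=1, sum(w)=200, sum(w^2)/sum(w)=100 -> tau2=1/100.
        assert dl_tau2(two_periods()) == pytest.approx(0.01, abs=1e-14)

    def test_truncation_at_zero(self):
        ests = [PeriodEstimate(f"p{i}", 0.5, 0.01) for i in range(6)]
        assert dl_tau2(ests) == 0.0
        nearly = two_periods(0.5, 0.5 + np.sqrt(0.01 * 0.999 * 2) / 2)
        assert dl_tau2(nearly) >= 0.0

    def test_never_negative_over_fuzz(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            assert dl_tau2(random_estimates(rng)) >= 0.0


class TestRandomEffect:
    def test_hand_example(self):
        res = random_effect(two_periods())
        assert res.tau2 == pytest.approx(0.01, abs=1e-14)
        assert res.estimate == pytest.approx(0.6, abs=1e-14)
        assert res.se == pytest.approx(np.sqrt(0.02 / 2), abs=1e-14)

    def test_reduces_to_fixed_when_tau2_zero(self):
        ests = [PeriodEstimate(f"p{i}", 0.5, 0.01 + 0.001 * i) for i in range(5)]
        assert dl_tau2(ests) == 0.0
        f, r = fixed_effect(ests), random_effect(ests)
        assert r.estimate == pytest.approx(f.estimate, abs=1e-14)
        assert r.se == pytest.approx(f.se, abs=1e-14)

    def test_huge_tau2_converges_to_simple_average(self):
        # Spread far exceeding the sampling variances: tau2 dwarfs every V_m
        # and the weights equalise.
        ests = [PeriodEstimate("p1", 0.1, 1e-6),
                PeriodEstimate("p2", 0.5, 3e-6),
                PeriodEstimate("p3", 0.9, 2e-6)]
        r = random_effect(ests)
        a = averaged(ests)
        assert r.tau2 > 1000 * max(e.V_wm for e in ests)
        assert r.estimate == pytest.approx(a.estimate, abs=1e-4)

    def test_se_at_least_fixed_when_heterogeneous(self):
        rng = np.random.default_rng(3)
        seen = 0
        while seen < 50:
            ests = random_estimates(rng)
            if dl_tau2(ests) == 0.0:
                continue
            assert random_effect(ests).se >= fixed_effect(ests).se
            seen += 1

    def test_random_between_fixed_and_average_for_two_periods(self):
        """With two periods the relative weight of the more precise period
        shrinks monotonically as tau2 grows, so the random-effects estimate
        falls weakly between the fixed estimate and the simple average.
        (With three or more periods the path from fixed to average need not
        stay inside the interval, so between-ness is only guaranteed here.)"""
        rng = np.random.default_rng(4)
        seen = 0
        while seen < 100:
            ests = random_estimates(rng, g=2)
            if dl_tau2(ests) == 0.0:
                continue
            f = fixed_effect(ests).estimate
            r = random_effect(ests).estimate
            a = averaged(ests).estimate
            lo, hi = min(f, a), max(f, a)
            assert lo - 1e-10 <= r <= hi + 1e-10
            seen += 1

    def test_random_typically_between_fixed_and_average_in_study_conditions(self):
        """For studies like the motivating one (inverse-variance weights of
        the same order across periods) the random-effects estimate lands
        between fixed and averaged, as observed empirically for every
        weighting scheme."""
        rng = np.random.default_rng(6)
        seen = 0
        while seen < 50:
            cfg = SimConfig(seed=int(rng.integers(2**31)), tau=0.15)
            pairs = simulate_study(cfg).pairs_by_period
            report = analyze_study(pairs, "A4")
            if report.random is None or report.random.tau2 == 0.0:
                continue
            lo = min(report.fixed.estimate, report.averaged.estimate)
            hi = max(report.fixed.estimate, report.averaged.estimate)
            assert lo - 0.01 <= report.random.estimate <= hi + 0.01
            seen += 1

    def test_pooled_estimates_within_range_of_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            ests = random_estimates(rng)
            ks = [e.kappa_wm for e in ests]
            for res in (fixed_effect(ests), random_effect(ests), averaged(ests)):
                assert min(ks) - 1e-12 <= res.estimate <= max(ks) + 1e-12


class TestAveraged:
    def test_mean_and_se(self):
        res = averaged(two_periods(v1=0.01, v2=0.03))
        assert res.estimate == pytest.approx(0.6, abs=1e-14)
        assert res.se == pytest.approx(np.sqrt(0.04 / 4), abs=1e-14)

    def test_single_period(self):
        res = averaged([PeriodEstimate("p1", 0.37, 0.02)])
        assert res.estimate == pytest.approx(0.37)
        assert res.se == pytest.approx(np.sqrt(0.02), abs=1e-14)


class TestStatsmodelsOracle:
    def test_matches_established_meta_analysis(self):
        """Fixed and DL random pooling agree with statsmodels'
        combine_effects (inverse-variance, DL) to 1e-8 on random fixtures.
        statsmodels leaves tau2 untruncated, hence the max(., 0)."""
        rng = np.random.default_rng(20)
        for _ in range(20):
            ests = random_estimates(rng)
            eff = np.array([e.kappa_wm for e in ests])
            var = np.array([e.V_wm for e in ests])
            sm = combine_effects(eff, var, method_re="dl")
            f = fixed_effect(ests)
            assert f.estimate == pytest.approx(sm.mean_effect_fe, abs=1e-8)
            assert f.se == pytest.approx(sm.sd_eff_w_fe, abs=1e-8)
            assert dl_tau2(ests) == pytest.approx(max(sm.tau2, 0.0), abs=1e-8)
            if sm.tau2 > 0:
                r = random_effect(ests)
                assert r.estimate == pytest.approx(sm.mean_effect_re, abs=1e-8)
                assert r.se == pytest.approx(sm.sd_eff_w_re, abs=1e-8)


class TestAnalyzeStudy:
    def _study_pairs(self, seed=7, **kw):
        cfg = SimConfig(seed=seed, **kw)
        return simulate_study(cfg).pairs_by_period

    def test_full_pipeline_shapes(self):
        report = analyze_study(self._study_pairs(), "A4")
        assert report.fixed is not None and report.random is not None
        assert report.averaged is not None
        assert len(report.period_estimates) + len(report.excluded) == 18
        assert report.collapsed_table.n == 18 * 20

    def test_collapsed_matches_direct_computation(self):
        pairs = self._study_pairs()
        report = analyze_study(pairs, "A4")
        direct = weighted_kappa(report.collapsed_table, named_scheme("A4"))
        assert report.collapsed.kappa == pytest.approx(direct.kappa)

    def test_one_period_study(self):
        pairs = self._study_pairs(g=1)
        report = analyze_study(pairs, "A4")
        only = next(iter(report.period_estimates.values()))
        assert report.collapsed.kappa == pytest.approx(only.kappa, abs=1e-14)
        assert report.fixed is None and report.random is None
        assert "at least two" in report.messages["pooling"]
        assert report.averaged.estimate == pytest.approx(only.kappa)

    def test_degenerate_periods_excluded_but_collapsed(self):
        pairs = self._study_pairs(g=4)
        pairs["degenerate"] = [("+c", "+c")]   # n=1: chance agreement is 1
        pairs["empty"] = []
        report = analyze_study(pairs, "A4")
        assert set(report.excluded) == {"degenerate", "empty"}
        assert report.collapsed_table.n == 4 * 20 + 1
        assert len(report.period_estimates) == 4

    def test_tau2_truncation_gives_identical_fixed_and_random(self):
        # Homogeneous study (tau=0): pick a seed where DL truncates to 0.
        for seed in range(30):
            pairs = self._study_pairs(seed=seed, tau=0.0, n_m=60)
            report = analyze_study(pairs, "A4")
            if report.random.tau2 == 0.0:
                assert report.random.estimate == pytest.approx(
                    report.fixed.estimate, abs=1e-12
                )
                assert "truncated" in report.messages["tau2"]
                break
        else:
            pytest.fail("no homogeneous study produced a truncated tau2")

    def test_empty_study_errors(self):
        with pytest.raises(EmptyStudyError):
            analyze_study({}, "A4")
        with pytest.raises(EmptyStudyError):
            analyze_study({"p1": []}, "A4")
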