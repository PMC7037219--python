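"""Non-compartmental analysis and the Monte-Carlo Dunnett comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fusionpk.model import analytic_plasma_auc_inf, simulate
from fusionpk.nca import (
    auc_trapezoid,
    compare_assays,
    dunnett_critical_value,
    dunnett_mc,
    nca_profile,
    nca_report,
    round_sig,
    terminal_halflife,
    tumor_plasma_ratio,
)


class TestAUC:
    def test_rectangle(self):
        assert auc_trapezoid([0.0, 1.0], [10.0, 10.0]) == pytest.approx(10.0)

    def test_triangle(self):
        assert auc_trapezoid([0.0, 1.0, 2.0], [0.0, 1.0, 0.0]) == pytest.approx(1.0)

    def test_against_piecewise_integral_oracle(self):
        rng = np.random.default_rng(2)
        times = np.sort(rng.uniform(0, 100, 50))
        times += np.arange(50) * 1e-6  # strictly increasing
        concs = rng.lognormal(0, 1, 50)
        # oracle: integrate each linear segment in closed form, summed
        expected = sum(
            (times[i + 1] - times[i]) * (concs[i] + concs[i + 1]) / 2.0
            for i in range(49)
        )
        assert auc_trapezoid(times, concs) == pytest.approx(expected, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            auc_trapezoid([1.0], [1.0])

    @given(st.integers(1, 48))
    def test_additive_over_partition(self, split):
        rng = np.random.default_rng(4)
        times = np.linspace(0, 336, 50)
        concs = rng.lognormal(0, 1, 50)
        total = auc_trapezoid(times, concs)
        left = auc_trapezoid(times[: split + 1], concs[: split + 1])
        right = auc_trapezoid(times[split:], concs[split:])
        assert left + right == pytest.approx(total, rel=1e-12)

    @given(st.integers(0, 19), st.floats(0.01, 10.0))
    def test_monotone_in_any_concentration(self, idx, bump):
        rng = np.random.default_rng(9)
        times = np.linspace(0, 100, 20)
        concs = rng.lognormal(0, 1, 20)
        bumped = concs.copy()
        bumped[idx] += bump
        assert auc_trapezoid(times, bumped) >= auc_trapezoid(times, concs)


class TestTerminalHalflife:
    def test_exact_exponential_recovers_halflife(self):
        # lambda_z chosen so t_half is ~98.1 h, the scale seen in vivo
        lam = math.log(2.0) / 98.1
        t = np.array([72.0, 168.0, 240.0, 336.0])
        c = 100.0 * np.exp(-lam * t)
        fit = terminal_halflife(t, c, n_points=3)
        assert fit.lambda_z == pytest.approx(lam, rel=1e-10)
        assert fit.t_half == pytest.approx(98.1, rel=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_profile_undefined(self):
        fit = terminal_halflife([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert math.isnan(fit.lambda_z) and math.isnan(fit.t_half)

    def test_matches_two_point_slope_on_collinear_data(self):
        t = np.array([10.0, 20.0, 30.0])
        c = np.exp(-0.05 * t) * 7.0
        fit = terminal_halflife(t, c)
        closed_form = -(math.log(c[2]) - math.log(c[0])) / (t[2] - t[0])
        assert fit.lambda_z == pytest.approx(closed_form, rel=1e-12)

    def test_nonpositive_concs_rejected(self):
        with pytest.raises(ValueError):
            terminal_halflife([1.0, 2.0, 3.0], [1.0, 0.0, 0.1])


class TestNCAProfile:
    def test_auc_inf_matches_analytic_oracle(self, ref_params):
        times = np.concatenate([[0.0], np.geomspace(0.05, 2000.0, 400)])
        sim = simulate(ref_params, 26.6, times)
        res = nca_profile(sim.times, sim.Cp, dose_ug_per_kg=1000.0)
        assert res.auc_inf == pytest.approx(
            analytic_plasma_auc_inf(ref_params, 26.6), rel=0.02)

    def test_cl_times_auc_is_dose(self):
        t = np.array([0.0, 1.0, 6.0, 24.0, 72.0, 168.0])
        c = 10.0 * np.exp(-0.02 * t)
        res = nca_profile(t, c, dose_ug_per_kg=1000.0)
        assert res.cl_per_kg * res.auc_inf == pytest.approx(1000.0)
        assert res.cl_last_per_kg * res.auc_last == pytest.approx(1000.0)

    def test_dose_scaling(self):
        t = np.array([0.0, 1.0, 6.0, 24.0, 72.0])
        c = 10.0 * np.exp(-0.03 * t)
        r1 = nca_profile(t, c)
        r10 = nca_profile(t, 10.0 * c)
        assert r10.auc_last == pytest.approx(10.0 * r1.auc_last)
        assert r10.auc_inf == pytest.approx(10.0 * r1.auc_inf)
        assert r10.t_half == pytest.approx(r1.t_half)

    def test_cmax_at_first_sample_for_declining_profile(self):
        t = np.array([5.0 / 60.0, 1.0, 6.0, 24.0])
        c = np.array([15.0, 14.0, 12.0, 8.0])
        res = nca_profile(t, c)
        assert res.cmax == 15.0
        assert res.tmax == pytest.approx(5.0 / 60.0)

    def test_undefined_terminal_phase_flagged(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        c = np.array([1.0, 2.0, 3.0, 4.0])  # rising profile
        res = nca_profile(t, c, dose_ug_per_kg=100.0)
        assert not res.terminal_defined
        assert math.isnan(res.auc_inf)
        assert res.cl_per_kg is None
        assert res.cl_last_per_kg is not None

    def test_auc_inf_at_least_auc_last(self):
        t = np.array([0.0, 24.0, 72.0, 168.0, 336.0])
        c = 20.0 * np.exp(-0.01 * t)
        res = nca_profile(t, c)
        assert res.auc_inf >= res.auc_last
        assert res.t_half == pytest.approx(math.log(2.0) / res.lambda_z)


class TestRatios:
    def test_study_scale_ratios(self):
        assert tumor_plasma_ratio(229.0, 1470.0) == pytest.approx(0.156)
        assert tumor_plasma_ratio(2210.0, 16200.0) == pytest.approx(0.136)

    def test_equal_aucs(self):
        assert tumor_plasma_ratio(5.0, 5.0) == 1.0

    def test_zero_plasma_rejected(self):
        with pytest.raises(ValueError):
            tumor_plasma_ratio(1.0, 0.0)

    def test_round_sig(self):
        assert round_sig(0.15578, 3) == 0.156
        assert round_sig(16234.0, 3) == 16200.0
        assert round_sig(0.0) == 0.0


class TestDunnett:
    def test_single_comparison_reduces_to_t_critical_value(self):
        crit = dunnett_critical_value([50], 50, alpha=0.05,
                                      n_draws=400_000, seed=3)
        t_crit = stats.t.ppf(0.975, 98)
        assert crit == pytest.approx(t_crit, rel=0.01)

    def test_statistics_and_p_match_independent_implementation(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(0.5, 1, 10), rng.normal(0, 1, 10)]
        control = rng.normal(0, 1, 10)
        mine = dunnett_mc(groups, control, n_draws=200_000, seed=7)
        ref = stats.dunnett(*groups, control=control)
        np.testing.assert_allclose(mine.statistic, ref.statistic, rtol=1e-12)
        np.testing.assert_allclose(mine.p_adjusted, ref.pvalue, atol=0.01)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(1)
        g = [rng.normal(0, 1, 8), rng.normal(0, 1, 8)]
        c = rng.normal(0, 1, 8)
        a = dunnett_mc(g, c, n_draws=50_000, seed=123)
        b = dunnett_mc(g, c, n_draws=50_000, seed=123)
        assert np.array_equal(a.p_adjusted, b.p_adjusted)
        assert a.critical_value == b.critical_value

    def test_type_one_error_rate(self):
        # 3 groups of n=10 from the same normal: familywise rejection ~5%
        crit = dunnett_critical_value([10, 10], 10, alpha=0.05,
                                      n_draws=100_000, seed=11)
        rng = np.random.default_rng(13)
        rejections = 0
        n_trials = 1000
        for _ in range(n_trials):
            a, b, control = rng.normal(0.0, 1.0, (3, 10))
            res = stats_t_contrasts(a, b, control)
            if np.any(np.abs(res) > crit):
                rejections += 1
        rate = rejections / n_trials
        assert rate == pytest.approx(0.05, abs=0.02)


def stats_t_contrasts(a, b, control):
    """Dunnett t statistics computed directly from their definition."""
    df = 30 - 3
    s2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
          + np.sum((control - control.mean()) ** 2)) / df
    denom = math.sqrt(s2 * (1 / 10 + 1 / 10))
    return np.array([(a.mean() - control.mean()) / denom,
                     (b.mean() - control.mean()) / denom])


class TestCompareAssays:
    def test_generic_assay_underestimation_scale(self):
        cmp_res = compare_assays({"LBA": 2210.0, "ICMS_IGG4": 1480.0},
                                 reference="LBA")
        assert cmp_res.percent_difference["ICMS_IGG4"] == pytest.approx(33.0, abs=0.5)
        assert cmp_res.test_skipped

    def test_identical_groups_no_flag(self):
        rng = np.random.default_rng(21)
        base = rng.normal(100, 5, 6)
        cmp_res = compare_assays({"A": base, "B": base.copy()}, reference="A",
                                 n_draws=20_000, seed=2)
        assert cmp_res.percent_difference["B"] == pytest.approx(0.0)
        assert not cmp_res.dunnett_flags["B"]

    def test_replicates_run_anova_and_dunnett(self):
        rng = np.random.default_rng(0)
        groups = {
            "LBA": rng.normal(2210, 60, 5),
            "ICMS_IFNA": rng.normal(2210, 60, 5),
            "ICMS_IGG4": rng.normal(1480, 60, 5),
        }
        cmp_res = compare_assays(groups, reference="LBA", n_draws=50_000, seed=3)
        assert cmp_res.anova_p < 0.001
        assert cmp_res.dunnett_flags["ICMS_IGG4"]
        assert not cmp_res.dunnett_flags["ICMS_IFNA"]

    def test_reference_must_exist(self):
        with pytest.raises(ValueError):
            compare_assays({"A": 1.0, "B": 2.0}, reference="C")


class TestNCAReport:
    def test_report_covers_profiles_and_ratios(self, noise_free_dataset):
        report = nca_report(noise_free_dataset)
        assert set(report.matrix) == {"plasma", "tumor"}
        tumor = report[report.matrix == "tumor"]
        assert np.isfinite(tumor["tumor_plasma_auc_ratio"]).all()
        plasma = report[report.matrix == "plasma"]
        assert plasma["cl_per_kg"].notna().all()
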