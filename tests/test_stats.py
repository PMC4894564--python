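import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from scleromech.cohort import GeneratorConfig, generate_cohort
from scleromech.stats import (
    fit_age_genotype,
    fit_rigidity_model,
    group_summary,
    interval_weighted_iop,
    mean_iop,
    paired_ttest,
    pearson,
)


class TestFitAgeGenotype:
    def test_noise_free_cohort_recovers_printed_lines_exactly(self):
        df = generate_cohort(10, 10, seed=1,
                             config=GeneratorConfig.noise_free()).to_frame()
        fit = fit_age_genotype(df.E_star_MPa.values, df.age_months.values,
                               df.group.values, interaction=True)
        aff = fit.group_lines["affected"]
        nor = fit.group_lines["normal"]
        assert aff.slope == pytest.approx(0.05676, abs=1e-10)
        assert aff.intercept == pytest.approx(3.574, abs=1e-8)
        assert nor.slope == pytest.approx(0.04313, abs=1e-10)
        assert nor.intercept == pytest.approx(5.361, abs=1e-8)

    def test_interaction_lines_equal_separate_group_fits(self):
        df = generate_cohort(40, 40, seed=2).to_frame()
        fit = fit_age_genotype(df.E_star_MPa.values, df.age_months.values,
                               df.group.values, interaction=True)
        for grp in ("affected", "normal"):
            sub = df[df.group == grp]
            X = sm.add_constant(sub.age_months.values)
            sep = sm.OLS(sub.E_star_MPa.values, X).fit()
            assert fit.group_lines[grp].intercept == pytest.approx(
                sep.params[0], rel=1e-10)
            assert fit.group_lines[grp].slope == pytest.approx(
                sep.params[1], rel=1e-10)

    def test_large_cohort_slope_within_two_se(self):
        df = generate_cohort(5000, 5000, seed=3).to_frame()
        fit = fit_age_genotype(df.E_star_MPa.values, df.age_months.values,
                               df.group.values)
        line = fit.group_lines["affected"]
        assert abs(line.slope - 0.05676) < 2 * line.slope_se

    def test_group_contrast_direction_affected_lower(self):
        # at matched ages the affected group has the lower complex modulus
        df = generate_cohort(400, 400, seed=4).to_frame()
        fit = fit_age_genotype(df.E_star_MPa.values, df.age_months.values,
                               df.group.values, interaction=False)
        normal_effect = fit.term("group[normal]")
        assert normal_effect.coef > 0
        assert fit.group_p is not None and fit.group_p < 0.05

    def test_too_small_group_rejected(self):
        y = np.arange(6.0)
        age = np.arange(6.0)
        grp = np.array(["affected"] * 4 + ["normal"] * 2)
        with pytest.raises(ValueError, match="at least 3"):
            fit_age_genotype(y, age, grp, interaction=True)

    def test_missing_values_rejected(self):
        y = np.array([1.0, np.nan, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="non-finite"):
            fit_age_genotype(y, np.arange(6.0),
                             np.array(["affected"] * 3 + ["normal"] * 3))


class TestFitRigidityModel:
    def test_exact_on_noise_free_plane(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(5, 131, 50)
        iop = rng.uniform(10, 60, 50)
        k = 181.1 + 0.995 * age - 2.940 * iop
        fit = fit_rigidity_model(k, age, iop)
        assert fit.term("intercept").coef == pytest.approx(181.1, abs=1e-8)
        assert fit.term("age").coef == pytest.approx(0.995, abs=1e-10)
        assert fit.term("last_iop").coef == pytest.approx(-2.940, abs=1e-10)

    def test_iop_coefficient_negative_and_within_two_se(self):
        df = generate_cohort(2000, 1, seed=6).to_frame()
        aff = df[df.group == "affected"]
        fit = fit_rigidity_model(aff.k_norm.values, aff.age_months.values,
                                 aff.last_iop_mmHg.values)
        t = fit.term("last_iop")
        assert t.coef < 0
        assert abs(t.coef - (-2.940)) < 2 * t.se

    def test_collinear_covariates_rejected(self):
        age = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            fit_rigidity_model(age * 2, age, age)


class TestPearson:
    def test_perfect_linear_association(self):
        x = np.arange(10.0)
        r, p, n = pearson(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_null_association_is_small(self):
        rng = np.random.default_rng(7)
        r, p, _ = pearson(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(r) < 0.03

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            pearson(np.arange(2.0), np.arange(2.0))


class TestPairedTtest:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p, d = paired_ttest(a, a)
        assert t == 0.0 and np.isnan(p) or p == pytest.approx(1.0)
        assert d == 0.0

    def test_detects_anterior_posterior_thickness_difference(self):
        # anterior sclera thinner than posterior by a fixed offset >> noise
        rng = np.random.default_rng(8)
        post = rng.normal(0.49, 0.02, 25)
        ant = post - 0.18 + rng.normal(0, 0.01, 25)
        t, p, d = paired_ttest(ant, post)
        assert p < 1e-3 and d < 0

    def test_too_short(self):
        with pytest.raises(ValueError):
            paired_ttest(np.array([1.0]), np.array([2.0]))


class TestGroupSummary:
    def test_constant_property(self):
        df = pd.DataFrame({
            "group": ["affected"] * 5 + ["normal"] * 5,
            "age_months": np.arange(10.0) * 10 + 5,
            "E_star_MPa": 5.0,
        })
        out = group_summary(df, ["E_star_MPa"])
        assert out.loc["E_star_MPa", "affected_mean"] == 5.0
        assert out.loc["E_star_MPa", "affected_sd"] == 0.0

    def test_table_layout_for_default_cohort(self, default_cohort):
        df = default_cohort.to_frame()
        props = ["thickness_post_mm", "E_star_MPa", "tan_delta", "AB_MPa", "B"]
        out = group_summary(df, props)
        assert list(out.index) == props
        for col in ("affected_mean", "affected_sd", "normal_mean", "normal_sd", "p"):
            assert col in out.columns

    def test_affected_mean_near_generator_target(self):
        # mean E* at the cohort mean age of the affected line, n=15 draws
        df = generate_cohort(15, 10, seed=9).to_frame()
        out = group_summary(df, ["E_star_MPa"])
        cfg = GeneratorConfig.table_calibrated()
        line = cfg.line("E_star", "affected")
        ages = df[df.group == "affected"].age_months
        expected = line.at(ages).mean()
        sd = df[df.group == "affected"].E_star_MPa.std()
        assert abs(out.loc["E_star_MPa", "affected_mean"] - expected) < 3 * sd / np.sqrt(15)

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"group": ["affected"] * 3, "age_months": [1.0, 2, 3],
                           "E_star_MPa": [1.0, 2, 3]})
        out = group_summary(df, ["E_star_MPa"])  # single group: no p-value
        assert np.isnan(out.loc["E_star_MPa", "p"])


class TestIopSummaries:
    def test_mean_iop(self):
        assert mean_iop(np.array([10.0, 20.0])) == 15.0
        with pytest.raises(ValueError):
            mean_iop(np.array([]))

    def test_interval_weighted_mean_over_last_window(self):
        ages = np.array([0.0, 50.0, 96.0, 108.0, 120.0])
        iops = np.array([99.0, 99.0, 10.0, 20.0, 30.0])
        # only the last 24 months count: trapezoid of (10, 20, 30) over (96..120)
        w = interval_weighted_iop(ages, iops, window_months=24.0)
        assert w == pytest.approx(20.0)

    def test_single_reading_fallback(self):
        assert interval_weighted_iop(np.array([100.0]), np.array([17.0])) == 17.0
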