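import numpy as np
import pandas as pd
import pytest

from scleromech.cohort import (
    AnimalRecord,
    GeneratorConfig,
    RawNoise,
    calibrate_link_sigma,
    generate_cohort,
    generate_iop_history,
    render_raw_records,
    resid_sd_for_correlation,
)
from scleromech.pipeline import analyze_bundle, analyze_cohort


class TestGenerateCohort:
    def test_zero_residual_puts_every_property_on_its_line(self):
        cfg = GeneratorConfig.noise_free()
        cohort = generate_cohort(6, 6, seed=3, config=cfg)
        for row in cohort.rows:
            a, t = row.animal, row.truth
            if a.group == "affected":
                assert t.E_star == pytest.approx(3.574 + 0.05676 * a.age, rel=1e-9)
                assert t.tan_delta == pytest.approx(0.11253 - 0.000252 * a.age, rel=1e-9)
                assert t.AB == pytest.approx(0.503 + 0.03196 * a.age, rel=1e-9)
            else:
                assert t.E_star == pytest.approx(5.361 + 0.04313 * a.age, rel=1e-9)
                assert t.tan_delta == pytest.approx(0.12803 - 0.000342 * a.age, rel=1e-9)
                assert t.AB == pytest.approx(0.585 + 0.0256 * a.age, rel=1e-9)

    def test_affected_line_at_example_age(self):
        # 3.574 + 0.05676 * 38.4 = 5.754 MPa
        cfg = GeneratorConfig.noise_free()
        line = cfg.line("E_star", "affected")
        assert line.at(38.4) == pytest.approx(5.754, abs=5e-4)

    def test_same_seed_reproduces_table_exactly(self):
        a = generate_cohort(5, 5, seed=7).to_frame()
        b = generate_cohort(5, 5, seed=7).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_truth_invariants_hold_under_noise(self):
        cohort = generate_cohort(200, 100, seed=5)
        df = cohort.to_frame()
        assert (df.E_star_MPa > 0).all()
        assert df.tan_delta.between(0, 1, inclusive="neither").all()
        assert np.allclose(df.AB_MPa, df.A_MPa * df.B)
        assert (df.Rc_15 <= 0).all()
        assert (df.K_per_uL > 0).all()
        assert np.allclose(df.k_norm, df.K_per_uL * df.v0_uL)

    def test_group_marginal_sds_match_calibration_targets(self):
        # table calibration: affected E* SD ~2.85 MPa, tan δ SD ~0.017
        df = generate_cohort(8000, 1, seed=13).to_frame()
        aff = df[df.group == "affected"]
        assert aff.E_star_MPa.std() == pytest.approx(2.85, rel=0.05)
        assert aff.tan_delta.std() == pytest.approx(0.017, rel=0.08)

    def test_b_and_thickness_decline_with_age(self):
        df = generate_cohort(4000, 1, seed=17).to_frame()
        aff = df[df.group == "affected"]
        assert np.corrcoef(aff.B, aff.age_months)[0, 1] < -0.2
        assert np.corrcoef(aff.thickness_post_mm, aff.age_months)[0, 1] < -0.5

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_cohort(0, 5, seed=1)
        with pytest.raises(ValueError):
            generate_cohort(5, 5, age_low=100, age_high=10, seed=1)
        with pytest.raises(KeyError, match="no line"):
            cfg = GeneratorConfig(lines={})
            generate_cohort(2, 2, seed=1, config=cfg)

    def test_written_table_carries_seed_header(self, tmp_path):
        cohort = generate_cohort(3, 3, seed=21)
        path = tmp_path / "cohort.csv"
        cohort.write(path)
        text = path.read_text()
        assert text.startswith("#") and "seed=21" in text
        df = pd.read_csv(path, comment="#")
        assert len(df) == 6


class TestResidualCalibration:
    def test_correlation_identity(self):
        # r = slope·σ_age / sqrt(slope²σ_age² + σ²)
        sd = resid_sd_for_correlation(slope=0.05676, age_sd=36.37, r=0.857)
        implied = 0.05676 * 36.37 / np.hypot(0.05676 * 36.37, sd)
        assert implied == pytest.approx(0.857, rel=1e-9)

    def test_correlation_matched_config_hits_target(self):
        cfg = GeneratorConfig.table_calibrated().correlation_matched("E_star", 0.857)
        df = generate_cohort(5000, 1, seed=23, config=cfg).to_frame()
        aff = df[df.group == "affected"]
        r = np.corrcoef(aff.E_star_MPa, aff.age_months)[0, 1]
        assert r == pytest.approx(0.857, abs=0.02)

    def test_link_sigma_calibration_reproducible(self):
        s1 = calibrate_link_sigma(-0.744, link="tc", n=50_000, seed=2)
        s2 = calibrate_link_sigma(-0.744, link="tc", n=50_000, seed=2)
        assert s1 == s2 > 0


class TestIopHistory:
    def test_normal_eyes_stay_in_normotensive_band(self):
        for seed in range(20):
            animal = AnimalRecord(id=f"N{seed}", group="normal", age=80.0)
            h = generate_iop_history(animal, seed=seed)
            assert np.all((h.iops >= 8.0) & (h.iops <= 16.0))

    def test_preonset_affected_near_baseline(self):
        # an affected 5.6-month eye is still normotensive (~15-16 mmHg)
        vals = [
            generate_iop_history(
                AnimalRecord(id="A", group="affected", age=5.6), seed=s
            ).last_iop
            for s in range(50)
        ]
        assert abs(np.mean(vals) - 15.0) < 1.5
        assert np.std(vals) < 3.0

    def test_age_iop_correlation_positive_in_affected(self):
        df = generate_cohort(2000, 1, seed=29).to_frame()
        aff = df[df.group == "affected"]
        assert np.corrcoef(aff.age_months, aff.last_iop_mmHg)[0, 1] > 0.3

    def test_history_ends_at_animal_age(self):
        animal = AnimalRecord(id="A", group="affected", age=61.7)
        h = generate_iop_history(animal, seed=3)
        assert h.ages[-1] == pytest.approx(61.7)
        assert h.last_iop == h.iops[-1]


class TestRawRecordClosure:
    def test_noise_free_bundle_recovers_truth(self, noise_free_cohort):
        row = noise_free_cohort.rows[0]
        bundle = render_raw_records(row.truth, row.animal, seed=1,
                                    noise=RawNoise.zero())
        rec = analyze_bundle(bundle)
        t = row.truth
        assert rec["K_per_uL"] == pytest.approx(t.K, rel=1e-4)
        assert rec["k_norm"] == pytest.approx(t.k_norm, rel=1e-4)
        assert rec["E_star_MPa"] == pytest.approx(t.E_star, rel=1e-4)
        assert rec["tan_delta"] == pytest.approx(t.tan_delta, rel=1e-4)
        assert rec["A_MPa"] == pytest.approx(t.A, rel=1e-4)
        assert rec["B"] == pytest.approx(t.B, rel=1e-4)

    def test_fixed_seed_bundle_is_reproducible(self, default_cohort):
        row = default_cohort.rows[0]
        b1 = render_raw_records(row.truth, row.animal, seed=9)
        b2 = render_raw_records(row.truth, row.animal, seed=9)
        np.testing.assert_array_equal(b1.infusion_traces[0].iop,
                                      b2.infusion_traces[0].iop)
        np.testing.assert_array_equal(b1.ramp_stress, b2.ramp_stress)
        k = (1.0, 0.04)
        np.testing.assert_array_equal(b1.dma_series[k].stress, b2.dma_series[k].stress)

    def test_mean_recovery_under_default_noise(self):
        # 200 replicate eyes with identical truth: mean recovered E* within 2%
        cohort = generate_cohort(1, 1, seed=31)
        truth = cohort.rows[0].truth
        rng = np.random.default_rng(33)
        vals = [
            analyze_bundle(render_raw_records(truth, cohort.rows[0].animal,
                                              seed=rng))["E_star_MPa"]
            for _ in range(200)
        ]
        assert abs(np.mean(vals) - truth.E_star) / truth.E_star < 0.02


def test_analyze_cohort_produces_one_row_per_eye(default_cohort):
    df = analyze_cohort(default_cohort, seed=35, noise=RawNoise.zero())
    assert len(df) == 25
    truth = default_cohort.to_frame()
    np.testing.assert_allclose(df.E_star_MPa, truth.E_star_MPa, rtol=1e-4)
    assert set(df.group) == {"affected", "normal"}
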