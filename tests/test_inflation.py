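import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scleromech.inflation import (
    RFFramePair,
    _tissue_to_beam,
    default_pressure_schedule,
    inflation_series,
    ls_strain,
    simulate_speckle_pair,
    to_tissue_strains,
    track_displacement,
    DisplacementField,
)

SMALL = dict(n_axial=512, n_lateral=64)  # compact phantom for fast tests


def test_default_schedule_matches_protocol():
    sched = default_pressure_schedule()
    fine = sched[sched <= 20.0]
    assert len(fine) == 31  # 30 steps of 0.5 mmHg from 5 to 20
    assert np.allclose(np.diff(fine), 0.5)
    assert np.allclose(sched[31:], [22.5, 25.0, 27.5, 30.0, 35.0, 40.0, 45.0])


class TestTrackDisplacement:
    def test_integer_rigid_shift_recovered_exactly(self):
        pair = simulate_speckle_pair(axial_shift=3 * 1540 / (2 * 500e6) * 1e3,
                                     seed=1, **SMALL)
        d = track_displacement(pair)
        shifts = d.axial_disp / pair.axial_spacing
        assert np.allclose(shifts, 3.0, atol=0.02)
        assert d.correlation.min() > 0.99

    def test_subsample_shift_within_tenth_sample(self):
        pair = simulate_speckle_pair(axial_shift=2.5 * 1540 / (2 * 500e6) * 1e3,
                                     seed=2, **SMALL)
        d = track_displacement(pair)
        mean_shift = float((d.axial_disp / pair.axial_spacing).mean())
        assert abs(mean_shift - 2.5) < 0.1

    def test_decorrelated_pair_flagged_invalid(self):
        a = simulate_speckle_pair(seed=3, **SMALL)
        b = simulate_speckle_pair(seed=4, **SMALL)
        pair = RFFramePair(pre=a.pre, post=b.pre)  # independent scatterers
        d = track_displacement(pair)
        # nearly every node is flagged, far beyond the 20% eye-exclusion rule
        assert d.valid.mean() < 0.1

    def test_kernel_must_fit(self):
        pair = simulate_speckle_pair(seed=5, n_axial=256, n_lateral=16)
        with pytest.raises(ValueError, match="does not fit"):
            track_displacement(pair, kernel=(256, 16), search=(4, 2))


class TestLsStrain:
    @staticmethod
    def _field(disp_fn_ax, disp_fn_lat, n=(15, 12), valid=None):
        z = np.arange(n[0]) * 0.1
        x = np.arange(n[1]) * 0.05
        Z, X = np.meshgrid(z, x, indexing="ij")
        return DisplacementField(
            z=z, x=x, axial_disp=disp_fn_ax(Z, X), lateral_disp=disp_fn_lat(Z, X),
            correlation=np.ones(n),
            valid=np.ones(n, bool) if valid is None else valid,
        )

    def test_exact_for_affine_displacement(self):
        f = self._field(lambda Z, X: 0.01 * Z, lambda Z, X: -0.004 * X)
        s = ls_strain(f, strain_kernel=9)
        np.testing.assert_allclose(s.axial_strain, 0.01, rtol=1e-9)
        np.testing.assert_allclose(s.lateral_strain, -0.004, rtol=1e-9)

    def test_zero_field_gives_zero_strain(self):
        f = self._field(lambda Z, X: 0 * Z, lambda Z, X: 0 * X)
        s = ls_strain(f)
        assert np.all(s.axial_strain == 0) and np.all(s.lateral_strain == 0)

    def test_noise_suppression_vs_two_point_gradient(self):
        rng = np.random.default_rng(8)
        z = np.arange(60) * 0.1
        noise = rng.normal(0, 1e-3, (60, 40))
        disp = 0.01 * z[:, None] + noise
        f = DisplacementField(z=z, x=np.arange(40) * 0.05, axial_disp=disp,
                              lateral_disp=np.zeros_like(disp),
                              correlation=np.ones_like(disp),
                              valid=np.ones_like(disp, bool))
        s = ls_strain(f, strain_kernel=9)
        ls_sd = np.nanstd(s.axial_strain[10:-10] - 0.01)
        fd_sd = np.std(np.gradient(disp, z, axis=0)[10:-10] - 0.01)
        assert ls_sd < 0.35 * fd_sd  # ~1/sqrt(kernel) improvement

    def test_invalid_nodes_excluded_and_sparse_windows_missing(self):
        valid = np.ones((15, 12), bool)
        valid[:6, 0] = False  # starve the first column's top windows
        f = self._field(lambda Z, X: 0.01 * Z, lambda Z, X: 0.0 * X, valid=valid)
        f.axial_disp[:6, 0] = 99.0  # corrupt the invalid nodes
        s = ls_strain(f, strain_kernel=5)
        # windows with >=3 valid nodes are untouched by the corrupt values
        assert np.nanmax(np.abs(s.axial_strain[8:, 0] - 0.01)) < 1e-9
        # the fully starved windows are reported missing
        assert np.isnan(s.axial_strain[:2, 0]).all()

    def test_kernel_below_three_rejected(self):
        f = self._field(lambda Z, X: 0.01 * Z, lambda Z, X: 0.0 * X)
        with pytest.raises(ValueError):
            ls_strain(f, strain_kernel=2)


class TestCoordinateTransform:
    def test_identity_and_quarter_turn(self):
        t, r = to_tissue_strains(0.01, -0.004, 0.0, orientation=0.0)
        assert (t, r) == pytest.approx((-0.004, 0.01))
        t, r = to_tissue_strains(0.01, -0.004, 0.0, orientation=np.pi / 2)
        assert (t, r) == pytest.approx((0.01, -0.004))

    def test_pure_axial_strain_at_30_degrees(self):
        # tensor rotation: tangential = sin^2(30°)·ε_ax, radial = cos^2(30°)·ε_ax
        t, r = to_tissue_strains(0.01, 0.0, 0.0, orientation=np.pi / 6)
        assert t == pytest.approx(0.0025, rel=1e-9)
        assert r == pytest.approx(0.0075, rel=1e-9)

    @given(
        eax=st.floats(-0.03, 0.03),
        elat=st.floats(-0.03, 0.03),
        shear=st.floats(-0.01, 0.01),
        theta=st.floats(0, np.pi),
    )
    @settings(max_examples=100, deadline=None)
    def test_trace_preserved(self, eax, elat, shear, theta):
        t, r = to_tissue_strains(eax, elat, shear, orientation=theta)
        assert t + r == pytest.approx(eax + elat, abs=1e-12)

    @given(
        tang=st.floats(-0.03, 0.03),
        rad=st.floats(-0.03, 0.03),
        theta=st.floats(0, np.pi),
    )
    @settings(max_examples=50, deadline=None)
    def test_beam_frame_round_trip(self, tang, rad, theta):
        ax, lat, shear = _tissue_to_beam(tang, rad, theta)
        t, r = to_tissue_strains(ax, lat, shear, orientation=theta)
        assert t == pytest.approx(tang, abs=1e-12)
        assert r == pytest.approx(rad, abs=1e-12)


class TestSimulateSpecklePair:
    def test_zero_strain_pair_identical(self):
        pair = simulate_speckle_pair(axial_strain=0.0, lateral_strain=0.0,
                                     seed=6, **SMALL)
        np.testing.assert_array_equal(pair.pre, pair.post)

    def test_strain_specification_is_exclusive(self):
        with pytest.raises(ValueError, match="not both"):
            simulate_speckle_pair(axial_strain=0.01, tangential_strain=0.01)

    def test_large_strain_rejected(self):
        with pytest.raises(ValueError, match="5%"):
            simulate_speckle_pair(axial_strain=0.08)

    def test_transducer_constants(self):
        pair = simulate_speckle_pair(seed=7, **SMALL)
        assert pair.center_frequency == 55e6
        assert pair.axial_sample_rate == 500e6
        assert pair.axial_spacing * 1e3 == pytest.approx(1.54)


def test_inflation_series_smoke_and_failure_flag():
    # a short, coarse series: closure is checked at full scale elsewhere
    res = inflation_series(
        lambda p: 0.004 * (p - 5) / 10, lambda p: -0.004 * (p - 5) / 10,
        schedule=np.array([5.0, 10.0, 15.0]),
        seed=11, n_axial=512, n_lateral=64,
    )
    assert not res.tracking_failed
    assert res.Rc_15 < 0 < res.Tc_15
    assert len(res.pressures) == 3
    # a decorrelating series (huge noise) must flag failure and withhold Tc/Rc
    bad = inflation_series(
        lambda p: 0.004 * (p - 5) / 10, lambda p: -0.004 * (p - 5) / 10,
        schedule=np.array([5.0, 15.0]),
        seed=12, n_axial=512, n_lateral=64, noise_sd=50.0,
    )
    assert bad.tracking_failed and np.isnan(bad.Tc_15)
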