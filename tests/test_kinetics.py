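import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ultradce as u
from ultradce.errors import DomainError, GridMismatchError

DT_MIN = 1.695 / 60.0


class TestParameterMapping:
    def test_standard_start_maps_to_physiological_values(self):
        p = u.biexp_to_physio(u.BiexpParams(0.2, 0.2, 4.0))
        assert p.fp == pytest.approx(0.4)
        assert p.ps == pytest.approx(0.4)
        assert p.vp == pytest.approx(0.2)

    def test_zero_alpha_plus_collapses_to_one_compartment(self):
        p = u.biexp_to_physio(u.BiexpParams(0.0, 0.4, 4.0))
        assert p.fp == pytest.approx(0.4)
        assert p.ps == 0.0
        assert p.vp == pytest.approx(0.1)
        from ultradce.ranges import in_range
        assert not in_range("ps", np.array(p.ps))  # PS range is (0, 10]

    def test_mapping_verified_by_forward_curve_agreement(self):
        # (0.1, 0.3, 2) -> Fp=0.4, PS=2/15, vp=4/15: the two
        # parameterizations must produce identical forward curves.
        b = u.BiexpParams(0.1, 0.3, 2.0)
        p = u.biexp_to_physio(b)
        assert p.fp == pytest.approx(0.4)
        assert p.ps == pytest.approx(0.13333, abs=1e-5)
        assert p.vp == pytest.approx(0.26667, abs=1e-5)
        t = np.arange(71) * DT_MIN
        aif = u.make_aif(u.AifSpec(arrival_s=0.0), 71).values
        np.testing.assert_allclose(
            u.forward_2cu(b, aif, t), u.forward_2cu_physio(p, aif, t),
            atol=1e-12)

    def test_degenerate_and_infinite_ps_errors(self):
        with pytest.raises(DomainError):
            u.biexp_to_physio(u.BiexpParams(0.0, 0.0, 4.0))
        with pytest.raises(DomainError):
            u.biexp_to_physio(u.BiexpParams(0.2, 0.0, 4.0))

    def test_physio_worked_example_inverse(self):
        b = u.physio_to_biexp(u.TwoCUParams(vp=0.2, ps=0.4, fp=0.4))
        assert (b.alpha_plus, b.alpha_minus, b.beta_minus) == \
            pytest.approx((0.2, 0.2, 4.0))
        b0 = u.physio_to_biexp(u.TwoCUParams(vp=0.1, ps=0.0, fp=0.4))
        assert (b0.alpha_plus, b0.alpha_minus, b0.beta_minus) == \
            pytest.approx((0.0, 0.4, 4.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(vp=st.floats(0.01, 5.0), ps=st.floats(0.001, 5.0),
           fp=st.floats(0.01, 5.0))
    def test_roundtrip_identity(self, vp, ps, fp):
        p = u.TwoCUParams(vp=vp, ps=ps, fp=fp)
        back = u.biexp_to_physio(u.physio_to_biexp(p))
        assert back.vp == pytest.approx(vp, rel=1e-10)
        assert back.ps == pytest.approx(ps, rel=1e-10)
        assert back.fp == pytest.approx(fp, rel=1e-10)


class TestDerivedParameters:
    def test_worked_example(self):
        d = u.derive_secondary(u.TwoCUParams(vp=0.2, ps=0.4, fp=0.4))
        assert d.mttp == pytest.approx(0.25)
        assert d.tc == pytest.approx(0.5)
        assert d.e == pytest.approx(0.5)
        assert d.ktrans == pytest.approx(0.2)

    def test_zero_ps_limit(self):
        d = u.derive_secondary(u.TwoCUParams(vp=0.1, ps=0.0, fp=0.4))
        assert d.e == 0.0 and d.ktrans == 0.0
        assert d.mttp == d.tc

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(vp=st.floats(0.01, 5.0), ps=st.floats(0.001, 5.0),
           fp=st.floats(0.01, 5.0))
    def test_algebraic_identities(self, vp, ps, fp):
        p = u.TwoCUParams(vp=vp, ps=ps, fp=fp)
        d = u.derive_secondary(p)
        b = u.physio_to_biexp(p)
        assert 0.0 <= d.e <= 1.0
        assert d.mttp <= d.tc + 1e-15
        assert d.ktrans == pytest.approx(b.alpha_plus, rel=1e-12)
        assert d.ktrans <= min(p.ps, p.fp) + 1e-12
        assert d.mttp == pytest.approx(1.0 / b.beta_minus, rel=1e-12)

    def test_zero_fp_undefined(self):
        with pytest.raises(DomainError):
            u.derive_secondary(u.TwoCUParams(vp=0.1, ps=0.1, fp=0.0))


class TestForwardModel:
    def test_unit_impulse_reproduces_impulse_response(self):
        # A unit-area triangular pulse centered on frame 1 acts as an
        # approximate delta: the output must track the impulse response
        # delayed by one frame.
        n = 71
        t = np.arange(n) * DT_MIN
        aif = np.zeros(n)
        aif[1] = 1.0 / DT_MIN  # piecewise-linear triangle, unit area
        b = u.BiexpParams(0.2, 0.2, 4.0)
        c = u.forward_2cu(b, aif, t)
        expected = b.alpha_plus + b.alpha_minus * np.exp(
            -b.beta_minus * (t[2:] - DT_MIN))
        np.testing.assert_allclose(c[2:], expected, rtol=2e-3)

    def test_boxcar_patlak_ramp(self):
        # alpha_minus ~ 0 with a boxcar AIF integrates to a ramp
        # C(t) = alpha_plus * min(t, T); the piecewise-linear boxcar
        # edge ends half a frame past its last nonzero sample.
        n, T_frames = 100, 40
        t = np.arange(n) * DT_MIN
        aif = np.zeros(n)
        aif[:T_frames] = 1.0
        b = u.BiexpParams(alpha_plus=0.3, alpha_minus=1e-12, beta_minus=4.0)
        c = u.forward_2cu(b, aif, t)
        expected = 0.3 * np.minimum(t, (T_frames - 0.5) * DT_MIN)
        np.testing.assert_allclose(c, expected, atol=1e-9)

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.1, 0.3, 0.4])
        with pytest.raises(GridMismatchError):
            u.forward_2cu(u.BiexpParams(0.2, 0.2, 4.0), np.ones(4), t)

    def test_convolution_matches_oversampled_quadrature(self, window_aif,
                                                        window_times_min):
        # Independent oracle: 100x-oversampled trapezoidal quadrature of
        # the convolution integral with a linearly interpolated AIF.
        b = u.BiexpParams(0.2, 0.2, 8.0)
        c = u.forward_2cu(b, window_aif.values, window_times_min)
        fine = np.linspace(window_times_min[0], window_times_min[-1],
                           100 * (len(window_times_min) - 1) + 1)
        aif_fine = np.interp(fine, window_times_min, window_aif.values)
        imp_fine = b.alpha_plus + b.alpha_minus * np.exp(-b.beta_minus * fine)
        oracle = np.zeros_like(window_times_min)
        for k, tk in enumerate(window_times_min):
            if k == 0:
                continue
            sel = fine <= tk + 1e-12
            s = fine[sel]
            integrand = np.interp(tk - s, fine, imp_fine) * aif_fine[sel]
            oracle[k] = np.trapezoid(integrand, s)
        scale = np.abs(oracle).max()
        assert np.abs(c - oracle).max() < 1e-3 * scale


class TestVoxelFit:
    def test_noiseless_recovery_from_standard_start(self, window_aif,
                                                    window_times_min):
        truth = u.BiexpParams(0.2, 0.2, 4.0)
        curve = u.forward_2cu(truth, window_aif.values, window_times_min)
        fit, diag = u.fit_2cu_voxel(curve, window_aif.values, window_times_min)
        assert diag.converged
        assert fit.alpha_plus == pytest.approx(0.2, rel=0.01)
        assert fit.alpha_minus == pytest.approx(0.2, rel=0.01)
        assert fit.beta_minus == pytest.approx(4.0, rel=0.01)

    def test_noiseless_recovery_far_from_start(self, window_aif,
                                               window_times_min):
        truth_p = u.TwoCUParams(vp=0.05, ps=0.1, fp=1.5)
        curve = u.forward_2cu(u.physio_to_biexp(truth_p), window_aif.values,
                              window_times_min)
        fit, diag = u.fit_2cu_voxel(curve, window_aif.values, window_times_min)
        p = u.biexp_to_physio(fit)
        assert p.vp == pytest.approx(0.05, rel=0.02)
        assert p.ps == pytest.approx(0.1, rel=0.02)
        assert p.fp == pytest.approx(1.5, rel=0.02)

    def test_zero_curve_returns_start_unconverged(self, window_aif,
                                                  window_times_min):
        fit, diag = u.fit_2cu_voxel(np.zeros(71), window_aif.values,
                                    window_times_min)
        assert not diag.converged
        assert (fit.alpha_plus, fit.alpha_minus, fit.beta_minus) == \
            (0.2, 0.2, 4.0)

    def test_ssr_never_worse_than_start(self, window_aif, window_times_min):
        rng = np.random.default_rng(5)
        truth = u.BiexpParams(0.1, 0.5, 6.0)
        curve = u.forward_2cu(truth, window_aif.values, window_times_min)
        curve = curve + rng.normal(0, 0.05, curve.shape)
        start_curve = u.forward_2cu(u.BiexpParams(0.2, 0.2, 4.0),
                                    window_aif.values, window_times_min)
        ssr_start = float(((start_curve - curve) ** 2).sum())
        _, diag = u.fit_2cu_voxel(curve, window_aif.values, window_times_min)
        assert diag.ssr <= ssr_start + 1e-12


class TestVolumeFit:
    def test_phantom_region_medians_recovered(self, small_phantom):
        series, masks, aif_true, truth = small_phantom
        res = u.run_patient(
            series, masks["artery"],
            [(masks["lesion"], dict(roi_id="L0", roi_type="lesion",
                                    zone="PZ", pirads=4, gg="2")),
             (masks["normal"], dict(roi_id="N0", roi_type="normal",
                                    zone="PZ", pirads=1, gg="neg"))])
        lesion_fp = res.maps["fp"].masked()[masks["lesion"].data]
        assert np.nanmedian(lesion_fp) == pytest.approx(0.4, rel=0.05)
        normal_vp = res.maps["vp"].masked()[masks["normal"].data]
        assert np.nanmedian(normal_vp) == pytest.approx(0.1, rel=0.05)

    def test_all_background_phantom_all_invalid(self):
        shape = (6, 6, 1)
        artery = np.zeros(shape, bool); artery[0, 0, 0] = True
        spec = u.PhantomSpec(shape=shape, artery_mask=artery, seed=0)
        series, masks, aif, _ = u.make_phantom(spec)
        arrival = u.detect_arrival(series.data[masks["artery"].data].mean(0))
        s0 = u.compute_baseline(series, arrival)
        conc = u.to_concentration(series, s0, arrival_frame=arrival)
        aif_x = u.extract_aif(conc, masks["artery"])
        tissue = ~masks["artery"].data
        maps = u.fit_2cu_volume(conc, aif_x, voxel_mask=tissue)
        for pmap in maps.values():
            assert pmap.valid[tissue].sum() == 0
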