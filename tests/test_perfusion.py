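"""Signal chain and Fermi deconvolution: oracles and invariances."""

import numpy as np
import pytest

from mprkit import perfusion as pf
from mprkit import synthetic as sy
from mprkit.core import ConcentrationCurve, SignalTimeSeries

from conftest import make_noiseless_curves


class TestExtractROICurve:
    def test_constant_image_gives_constant_curve(self, acq):
        stack = np.full((8, 8, acq.n_frames), 0.7)
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True
        s = pf.extract_roi_curve(stack, mask, acq.frame_times, acq.td_aif)
        np.testing.assert_allclose(s.values, 0.7, rtol=1e-14)

    def test_single_pixel_mask_returns_that_series(self, acq):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 0.5, (8, 8, acq.n_frames))
        mask = np.zeros((8, 8), bool)
        mask[3, 4] = True
        s = pf.extract_roi_curve(stack, mask, acq.frame_times, acq.td_aif)
        np.testing.assert_array_equal(s.values, stack[3, 4])

    def test_empty_mask_and_shape_mismatch_rejected(self, acq):
        stack = np.zeros((8, 8, acq.n_frames))
        with pytest.raises(ValueError, match="empty"):
            pf.extract_roi_curve(stack, np.zeros((8, 8), bool),
                                 acq.frame_times, acq.td_aif)
        with pytest.raises(ValueError, match="shape"):
            pf.extract_roi_curve(stack, np.ones((4, 4), bool),
                                 acq.frame_times, acq.td_aif)


class TestNormalizeByPD:
    def test_identity_and_scale_invariance(self, acq):
        s = SignalTimeSeries(times=acq.frame_times,
                             values=np.linspace(0.1, 0.4, acq.n_frames),
                             role="blood", td=acq.td_aif)
        np.testing.assert_array_equal(pf.normalize_by_pd(s, 1.0).values,
                                      s.values)
        raw = SignalTimeSeries(times=acq.frame_times, values=5.0 * s.values,
                               role="blood", td=acq.td_aif)
        np.testing.assert_allclose(pf.normalize_by_pd(raw, 5.0).values,
                                   s.values, rtol=1e-15)
        with pytest.raises(ValueError):
            pf.normalize_by_pd(s, 0.0)


class TestSignalToT1:
    def test_unit_exponent_definition(self):
        assert pf.signal_to_t1(1 - np.exp(-1.0), td=0.015) == \
            pytest.approx(0.015, rel=1e-12)

    @pytest.mark.parametrize("s, td, t1", [(0.009631, 0.015, 1.55),
                                           (0.038548, 0.057, 1.45)])
    def test_precontrast_inversions(self, s, td, t1):
        assert pf.signal_to_t1(s, td) == pytest.approx(t1, rel=1e-4)

    def test_domain_error_identifies_frame(self):
        with pytest.raises(ValueError, match=r"frame\(s\) \[2\]"):
            pf.signal_to_t1(np.array([0.1, 0.2, 1.5]), td=0.015)


class TestSeriesToDeltaR1:
    def test_precontrast_signal_maps_to_zero(self, acq):
        s0 = 1 - np.exp(-acq.td_tf / 1.45)
        s = SignalTimeSeries(times=acq.frame_times,
                             values=np.full(acq.n_frames, s0),
                             role="tissue", td=acq.td_tf)
        c = pf.series_to_delta_r1(s, baseline=None)
        np.testing.assert_allclose(c.delta_r1, 0.0, atol=1e-9)

    def test_known_t1_drop_arithmetic(self, acq):
        # T1 falls 1.45 -> 0.5 s: ΔR1 = 2 − 1/1.45
        vals = np.full(acq.n_frames, 1 - np.exp(-acq.td_tf / 0.5))
        s = SignalTimeSeries(times=acq.frame_times, values=vals,
                             role="tissue", td=acq.td_tf)
        c = pf.series_to_delta_r1(s, baseline=None)
        np.testing.assert_allclose(c.delta_r1, 2.0 - 1 / 1.45, rtol=1e-9)

    def test_round_trip_recovers_delta_r1(self, acq, aif_curve):
        s = sy.concentration_to_signal(aif_curve, acq, 1.55, role="blood")
        c = pf.series_to_delta_r1(s, baseline=None)
        np.testing.assert_allclose(c.delta_r1, aif_curve.delta_r1,
                                   rtol=1e-9, atol=1e-12)

    def test_strict_mode_propagates_domain_error(self, acq):
        vals = np.full(acq.n_frames, 0.02)
        vals[5] = -0.01
        s = SignalTimeSeries(times=acq.frame_times, values=vals,
                             role="tissue", td=acq.td_tf)
        with pytest.raises(ValueError, match="frame"):
            pf.series_to_delta_r1(s, strict=True)
        c = pf.series_to_delta_r1(s, strict=False, baseline=None)
        assert np.all(np.isfinite(c.delta_r1))


class TestConvolveTrapezoid:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pf.convolve_trapezoid(np.ones(5), np.ones(4), 0.1)

    def test_matches_direct_quadrature(self):
        rng = np.random.default_rng(1)
        dt = 0.12
        a = rng.uniform(0, 1, 20)
        h = rng.uniform(0, 1, 20)
        c = pf.convolve_trapezoid(a, h, dt)
        # direct trapezoid evaluation of the convolution integral
        for i in (1, 5, 19):
            integrand = a[:i + 1] * h[i::-1]
            expected = np.trapezoid(integrand, dx=dt)
            assert c[i] == pytest.approx(expected, rel=1e-12)


class TestFermiDeconvolve:
    @pytest.mark.parametrize("mbf", [2.0, 20.0])
    def test_noiseless_recovery(self, acq, aif_model, mbf):
        aif_c, tf_c = make_noiseless_curves(mbf, acq, aif_model)
        res = pf.fermi_deconvolve(aif_c, tf_c)
        assert res.mbf == pytest.approx(mbf, rel=0.02)
        assert not res.flagged

    def test_zero_tissue_curve_gives_zero_flow(self, aif_curve):
        tf = ConcentrationCurve(times=aif_curve.times,
                                delta_r1=np.zeros(aif_curve.times.size))
        res = pf.fermi_deconvolve(aif_curve, tf)
        assert res.mbf == 0.0

    def test_joint_scaling_invariance(self, acq, aif_model):
        aif_c, tf_c = make_noiseless_curves(6.0, acq, aif_model)
        res = pf.fermi_deconvolve(aif_c, tf_c)
        c = 3.7
        res_scaled = pf.fermi_deconvolve(
            ConcentrationCurve(aif_c.times, c * aif_c.delta_r1),
            ConcentrationCurve(tf_c.times, c * tf_c.delta_r1))
        assert res_scaled.mbf == pytest.approx(res.mbf, rel=1e-6)

    def test_constant_kernel_matches_linear_regression_oracle(self, aif_curve):
        # k = 0: model is tf = beta * cumint(aif) with beta = h(d+) = A/2,
        # so ordinary least squares on that regressor is an independent oracle
        from scipy.integrate import cumulative_trapezoid
        A = 0.14
        fermi = pf.FermiParams(A, 0.0, 1.0, 0.0)
        tf = sy.tissue_curve_from_fermi(aif_curve, fermi)
        n = pf.first_pass_window(aif_curve)
        x = cumulative_trapezoid(aif_curve.delta_r1[:n], aif_curve.times[:n],
                                 initial=0.0)
        beta = float(np.dot(x, tf.delta_r1[:n]) / np.dot(x, x))
        mbf_oracle = beta * 60.0 / 1.05
        res = pf.fermi_deconvolve(aif_curve, tf)
        assert res.mbf == pytest.approx(mbf_oracle, rel=0.01)

    def test_baseline_offset_invariance(self, acq, aif_model):
        # a constant tissue-signal offset that baseline correction removes
        aif = sy.gamma_variate_aif(aif_model, acq.frame_times)
        tf = sy.tissue_curve_from_fermi(aif, sy.fermi_for_mbf(6.0))
        st = sy.concentration_to_signal(tf, acq, 1.45, role="tissue")
        ref = pf.fermi_deconvolve(
            pf.series_to_delta_r1(
                sy.concentration_to_signal(aif, acq, 1.55, role="blood")),
            pf.series_to_delta_r1(st)).mbf
        shifted = SignalTimeSeries(times=st.times, values=st.values + 0.005,
                                   role="tissue", td=st.td)
        res = pf.fermi_deconvolve(
            pf.series_to_delta_r1(
                sy.concentration_to_signal(aif, acq, 1.55, role="blood")),
            pf.series_to_delta_r1(shifted)).mbf
        assert res == pytest.approx(ref, rel=0.01)

    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 0.1, 0.3, 0.35])
        a = ConcentrationCurve(times=t, delta_r1=np.ones(4))
        with pytest.raises(ValueError, match="uniform"):
            pf.fermi_deconvolve(a, a)


class TestComputeMPR:
    def _result(self, mbf, condition):
        return pf.PerfusionResult(mbf, pf.FermiParams(0.1, 0.5, 1.0, 0.0),
                                  0.0, condition)

    def test_equal_conditions_give_unity(self):
        r = self._result(4.0, "rest")
        s = self._result(4.0, "stress")
        assert pf.compute_mpr(r, s).mpr == 1.0

    def test_ratio_definition(self):
        assert pf.compute_mpr(self._result(1.0, "rest"),
                              self._result(2.0, "stress")).mpr == 2.0

    def test_zero_rest_flow_undefined(self):
        with pytest.raises(ValueError, match="excluded"):
            pf.compute_mpr(self._result(0.0, "rest"),
                           self._result(2.0, "stress"))
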