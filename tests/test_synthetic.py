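"""Phantom generators: closed-form values, determinism, validation."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from mprkit import perfusion as pf
from mprkit import synthetic as sy
from mprkit.core import AcquisitionParams


class TestGammaVariateAIF:
    def test_zero_before_and_at_arrival(self):
        a = sy.GammaVariateAIF(t0=1.0, t_peak=3.0, c_peak=1.0, alpha=2.0)
        assert a(np.array([0.0, 0.5, 1.0])).tolist() == [0.0, 0.0, 0.0]

    def test_peak_value_at_t_peak(self):
        a = sy.GammaVariateAIF(t0=0.6, t_peak=1.8, c_peak=12.0, alpha=3.0)
        t = np.linspace(0, 10, 5000)
        v = a(t)
        assert a(np.array([1.8]))[0] == pytest.approx(12.0)
        assert v.max() <= 12.0 + 1e-9

    def test_hand_computed_value(self):
        # alpha=2, t0=1, t_peak=3: at t=5, x=2 -> 2^2 * e^{2(1-2)} = 4 e^-2
        a = sy.GammaVariateAIF(t0=1.0, t_peak=3.0, c_peak=1.0, alpha=2.0)
        assert a(np.array([5.0]))[0] == pytest.approx(4 * np.exp(-2), rel=1e-12)

    def test_non_monotone_times_rejected(self):
        a = sy.GammaVariateAIF()
        with pytest.raises(ValueError, match="nondecreasing"):
            sy.gamma_variate_aif(a, np.array([0.0, 1.0, 0.5]))


class TestTissueCurveFromFermi:
    def test_interior_impulse_reproduces_shifted_kernel(self, acq):
        # discrete delta at an interior frame has full trapezoid weight, so
        # the convolution identity is exact there
        from mprkit.core import ConcentrationCurve
        dt = acq.frame_interval
        t = acq.frame_times
        a = np.zeros(t.size)
        a[1] = 1.0 / dt
        fermi = sy.fermi_for_mbf(4.0, delay=0.0)
        curve = sy.tissue_curve_from_fermi(
            ConcentrationCurve(times=t, delta_r1=a), fermi, dt=dt)
        expected = fermi(t - dt)
        np.testing.assert_allclose(curve.delta_r1[2:], expected[2:], rtol=1e-12)

    def test_constant_kernel_is_running_integral(self, aif_curve):
        # k = 0 degenerates the Fermi form to the constant A/2
        A = 0.2
        fermi = pf.FermiParams(A, 0.0, 1.0, 0.0)
        curve = sy.tissue_curve_from_fermi(aif_curve, fermi)
        expected = (A / 2) * cumulative_trapezoid(
            aif_curve.delta_r1, aif_curve.times, initial=0.0)
        np.testing.assert_allclose(curve.delta_r1, expected, rtol=1e-10, atol=1e-14)

    def test_linearity_in_aif(self, aif_curve):
        from mprkit.core import ConcentrationCurve
        fermi = sy.fermi_for_mbf(6.0)
        base = sy.tissue_curve_from_fermi(aif_curve, fermi).delta_r1
        scaled_in = ConcentrationCurve(times=aif_curve.times,
                                       delta_r1=3.5 * aif_curve.delta_r1)
        scaled = sy.tissue_curve_from_fermi(scaled_in, fermi).delta_r1
        np.testing.assert_allclose(scaled, 3.5 * base, rtol=1e-12)


class TestConcentrationToSignal:
    @pytest.mark.parametrize("t1_0, role, expected", [
        (1.55, "blood", 0.009631), (1.45, "tissue", 0.038548)])
    def test_precontrast_signal_levels(self, acq, t1_0, role, expected):
        from mprkit.core import ConcentrationCurve
        c = ConcentrationCurve(times=acq.frame_times,
                               delta_r1=np.zeros(acq.n_frames))
        s = sy.concentration_to_signal(c, acq, t1_0, role=role)
        np.testing.assert_allclose(s.values, expected, rtol=1e-4)

    def test_long_delay_fully_recovers(self):
        from mprkit.core import ConcentrationCurve
        acq = AcquisitionParams(td_tf=50.0, n_frames=3)
        c = ConcentrationCurve(times=acq.frame_times, delta_r1=np.zeros(3))
        s = sy.concentration_to_signal(c, acq, 1.45, role="tissue")
        np.testing.assert_allclose(s.values, 1.0, atol=1e-12)

    def test_negative_t1_rejected(self, acq):
        from mprkit.core import ConcentrationCurve
        c = ConcentrationCurve(times=acq.frame_times,
                               delta_r1=np.zeros(acq.n_frames))
        with pytest.raises(ValueError, match="t1_0"):
            sy.concentration_to_signal(c, acq, -1.0)

    @pytest.mark.parametrize("td_name,role", [("td_aif", "blood"),
                                              ("td_tf", "tissue")])
    def test_t1_round_trip_noiseless(self, aif_curve, acq, td_name, role):
        t1_0 = 1.55 if role == "blood" else 1.45
        s = sy.concentration_to_signal(aif_curve, acq, t1_0, role=role)
        t1_true = 1.0 / (1.0 / t1_0 + aif_curve.delta_r1)
        t1_rec = pf.signal_to_t1(s.values, getattr(acq, td_name))
        np.testing.assert_allclose(t1_rec, t1_true, rtol=1e-9)


class TestRenderPerfusionSeries:
    def test_noiseless_roi_means_match_closed_form(self, acq):
        ph = sy.PhantomGroundTruth(mbf_rest=4.0, mbf_stress=10.0, seed=3)
        rend = sy.render_perfusion_series(ph, acq)
        for cond, data in rend.conditions.items():
            blood = data.aif_stack[data.blood_mask].mean(axis=0)
            expect = sy.concentration_to_signal(
                data.aif_truth, acq, ph.t1_blood0, role="blood").values
            np.testing.assert_allclose(blood, expect, atol=1e-12)
            myo = data.tf_stack[data.myo_mask].mean(axis=0)
            expect = sy.concentration_to_signal(
                data.tf_truth, acq, ph.t1_myo0, role="tissue").values
            np.testing.assert_allclose(myo, expect, atol=1e-12)

    def test_same_seed_bit_identical(self, acq):
        ph = sy.PhantomGroundTruth(noise_sd=0.01, seed=11)
        a = sy.render_perfusion_series(ph, acq)
        b = sy.render_perfusion_series(ph, acq)
        for cond in a.conditions:
            np.testing.assert_array_equal(a.conditions[cond].aif_stack,
                                          b.conditions[cond].aif_stack)
            np.testing.assert_array_equal(a.conditions[cond].tf_stack,
                                          b.conditions[cond].tf_stack)

    def test_mpr_scales_with_stress_flow(self):
        a = sy.PhantomGroundTruth(mbf_rest=4.0, mbf_stress=8.0)
        b = sy.PhantomGroundTruth(mbf_rest=4.0, mbf_stress=16.0)
        assert b.mpr == pytest.approx(2 * a.mpr)

    def test_stress_below_rest_rejected(self):
        with pytest.raises(ValueError, match="mbf_stress"):
            sy.PhantomGroundTruth(mbf_rest=4.0, mbf_stress=2.0)


class TestRenderLVMasks:
    def test_annulus_closed_form_truth(self):
        _, truth = sy.render_lv_masks({"ED": (2.0, 3.0)}, n_slices=1)
        assert truth["ED"]["myo_volume_mm3"] == pytest.approx(
            np.pi * (9 - 4) * 1.0, rel=1e-12)
        assert truth["ED"]["mass_mg"] == pytest.approx(np.pi * 5 * 1.05)

    def test_zero_endo_radius_gives_zero_cavity(self):
        geom, truth = sy.render_lv_masks({"apex": (0.0, 2.0)}, n_slices=1)
        assert truth["apex"]["cavity_volume_ul"] == 0.0
        endo, _ = geom.phase("apex")
        assert endo.sum() == 0

    def test_refinement_reduces_rasterization_error(self):
        from mprkit import lv_function as lvf
        errs = {}
        for px, shape in [(0.2, (64, 64)), (0.1, (128, 128)),
                          (0.05, (256, 256))]:
            geom, truth = sy.render_lv_masks({"ED": (2.0, 3.0)}, n_slices=1,
                                             pixel_spacing=(px, px),
                                             image_shape=shape)
            v = lvf.cavity_volume(geom, "ED")
            errs[px] = abs(v / truth["ED"]["cavity_volume_ul"] - 1)
        assert errs[0.1] < 0.02
        assert errs[0.05] < errs[0.2]

    def test_epi_not_exceeding_endo_rejected(self):
        with pytest.raises(ValueError, match="epicardial"):
            sy.render_lv_masks({"ED": (3.0, 2.0)}, n_slices=1)


class TestRenderDisplacements:
    def test_identity_deformation_is_zero(self):
        d = sy.CylinderDeformation(r_endo_ref=1.5, r_epi_ref=2.9,
                                   r_endo_def=1.5)
        frames, truth = sy.render_displacements(d, n_frames=3)
        assert np.abs(frames.displacements).max() == 0.0
        assert np.abs(truth["ecc_peak_per_point"]).max() == 0.0

    def test_closed_form_ecc_at_known_ratio(self):
        # choose R so that r/R = 0.9 -> Ecc = (0.81 - 1)/2 = -0.095
        d = sy.CylinderDeformation(r_endo_ref=1.5, r_epi_ref=2.9,
                                   r_endo_def=1.0)
        R = np.sqrt(d.delta / (1 - 0.81))
        assert d.ecc(np.array([R]))[0] == pytest.approx(-0.095, rel=1e-12)

    def test_ecc_magnitude_decreases_transmurally(self):
        d = sy.CylinderDeformation()
        _, truth = sy.render_displacements(d, n_frames=2)
        R = truth["R"]
        order = np.argsort(R)
        ecc_sorted = truth["ecc_peak_per_point"][order]
        # |Ecc| nonincreasing with R (equal within rings)
        assert np.all(np.diff(np.abs(ecc_sorted)) <= 1e-12)

    def test_phase_encode_decode_round_trip(self):
        d = sy.CylinderDeformation()
        frames, _ = sy.render_displacements(d, n_frames=3)
        from mprkit.strain import decode_phase, encode_phase
        ke = 0.3
        u = frames.displacements[-1]
        np.testing.assert_allclose(decode_phase(encode_phase(u, ke), ke), u,
                                   atol=1e-15)
        with pytest.raises(ValueError, match="wrap"):
            encode_phase(u, ke=5.0)

    def test_collapsing_deformation_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            sy.CylinderDeformation(r_endo_def=0.0)


class TestGenerateGTT:
    def test_flat_profile_and_determinism(self):
        flat = sy.GTTProfile(baseline=100.0, excursion=0.0)
        rec, clipped = sy.generate_gtt(flat, noise_sd=0.0)
        np.testing.assert_array_equal(rec.glucose, 100.0)
        assert not clipped.any()
        a, _ = sy.generate_gtt(sy.GTTProfile(), noise_sd=15.0, seed=5)
        b, _ = sy.generate_gtt(sy.GTTProfile(), noise_sd=15.0, seed=5)
        np.testing.assert_array_equal(a.glucose, b.glucose)

    def test_tolerance_shaped_profile_peaks_after_baseline(self):
        rec, _ = sy.generate_gtt(sy.GTTProfile(), noise_sd=0.0)
        assert rec.glucose[1] > rec.glucose[0]  # 10 min above fasting


class TestGenerateCohort:
    def test_zero_sd_reproduces_means_exactly(self):
        profile = {"mpr": {"control": {24: (2.0, 0.0)},
                           "hfd": {24: (1.2, 0.0)}}}
        cfg = sy.CohortConfig(n_per_group=3, timepoints=(24,),
                              effect_profile=profile, seed=1)
        df = sy.generate_cohort(cfg)
        assert (df[df.group == "control"].mpr == 2.0).all()
        assert (df[df.group == "hfd"].mpr == 1.2).all()

    def test_configured_means_recovered_within_three_se(self):
        profile = {"mpr": {"control": {24: (2.0, 0.3)},
                           "hfd": {24: (1.2, 0.3)}}}
        cfg = sy.CohortConfig(n_per_group=8, timepoints=(24,),
                              effect_profile=profile, seed=42)
        df = sy.generate_cohort(cfg)
        se = 0.3 / np.sqrt(8)
        for grp, mu in (("control", 2.0), ("hfd", 1.2)):
            assert abs(df[df.group == grp].mpr.mean() - mu) < 3 * se

    def test_determinism_and_validation(self):
        cfg = sy.CohortConfig(n_per_group=2, seed=9)
        a, b = sy.generate_cohort(cfg), sy.generate_cohort(cfg)
        assert a.equals(b)
        bad = {"mpr": {"control": {24: (2.0, -0.1)}, "hfd": {24: (1.0, 0.1)}}}
        with pytest.raises(ValueError, match="negative SD"):
            sy.CohortConfig(n_per_group=2, timepoints=(24,),
                            effect_profile=bad)
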