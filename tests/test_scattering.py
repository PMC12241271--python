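"""GIWAXS reduction, peak deconvolution, pole figures, and closed forms."""

import numpy as np
import pytest

from cesakit import scattering as sc
from cesakit import synthetic_data as sd


def _blank_image(shape=(64, 96), distance=90.0):
    cal = sc.QCalibration(distance=distance,
                          beam_center=(float(shape[0] - 1),
                                       float(shape[1] // 2)))
    return sc.DetectorImage(intensity=np.zeros(shape), calibration=cal)


class TestQMap:
    def test_beam_center_pixel_is_q_zero(self):
        img = _blank_image()
        q, _ = sc.q_map(img)
        r0, c0 = img.calibration.beam_center
        assert q[int(r0), int(round(c0))] == pytest.approx(0.0, abs=1e-6)

    def test_pixel_straight_above_center_is_chi_zero(self):
        img = _blank_image(shape=(64, 97))  # odd → integer center column
        _, chi = sc.q_map(img)
        c0 = int(img.calibration.beam_center[1])
        assert chi[0, c0] == pytest.approx(0.0, abs=1e-9)

    def test_off_axis_pixel_matches_trigonometry_oracle(self):
        img = _blank_image()
        q, chi = sc.q_map(img)
        cal = img.calibration
        row, col = 10, 80
        dx = (col - cal.beam_center[1]) * cal.pixel_size
        dy = (cal.beam_center[0] - row) * cal.pixel_size
        two_theta = np.arctan(np.hypot(dx, dy) / cal.distance)
        q_expected = 4 * np.pi / cal.wavelength * np.sin(two_theta / 2)
        chi_expected = np.degrees(np.arctan2(dx, dy))
        assert q[row, col] == pytest.approx(q_expected, rel=1e-12)
        assert chi[row, col] == pytest.approx(chi_expected, rel=1e-12)

    def test_in_plane_rotation_shifts_chi_only(self):
        """Rotating pixel offsets about the beam axis preserves q."""
        img = _blank_image()
        q, chi = sc.q_map(img)
        # pixels at equal radius have equal q regardless of azimuth
        r0, c0 = img.calibration.beam_center
        assert q[int(r0) - 20, int(round(c0))] == pytest.approx(
            q[int(r0), int(round(c0)) + 20], rel=1e-9)


class TestSectorAndAzimuthal:
    def test_uniform_image_gives_flat_profiles(self):
        img = _blank_image()
        img.intensity[:] = 7.0
        prof = sc.sector_average(img)
        np.testing.assert_allclose(prof.intensity, 7.0)
        chi, inten = sc.azimuthal_profile(img, q_range=(0.2, 0.6))
        np.testing.assert_allclose(inten, 7.0)

    def test_wedge_90_equals_full_average(self):
        spec = sd.ScatterSpec(seed=1)
        giwaxs, _ = sd.synth_detector_image(spec)
        full = sc.sector_average(giwaxs, wedge_half_angle=90.0)
        q, chi = sc.q_map(giwaxs)
        sel = giwaxs.mask
        # independent full-azimuth binning
        edges = np.arange(0.0, q[sel].max() + 0.005, 0.005)
        counts, _ = np.histogram(q[sel], bins=edges)
        sums, _ = np.histogram(q[sel], bins=edges,
                               weights=giwaxs.intensity[sel])
        keep = counts > 0
        np.testing.assert_allclose(full.intensity, sums[keep] / counts[keep])

    def test_ring_confined_to_wedge_appears_at_q0(self):
        spec = sd.ScatterSpec(
            peaks=(sd.PeakModel(1.55, 0.02, 100.0, 10.0),),
            amorphous=sd.PeakModel(1.4, 0.15, 0.0), background=0.0, seed=0)
        giwaxs, _ = sd.synth_detector_image(spec)
        prof = sc.sector_average(giwaxs)
        assert prof.q[np.argmax(prof.intensity)] == pytest.approx(1.55,
                                                                  abs=0.005)

    def test_empty_annulus_errors(self):
        img = _blank_image()
        with pytest.raises(ValueError, match="empty annulus"):
            sc.azimuthal_profile(img, q_range=(50.0, 60.0))


class TestPeakFit:
    def test_noiseless_model_profile_recovered_exactly(self):
        q = np.arange(1.1, 1.95, 0.005)
        truth = dict(bg=3.0, a200=40.0, c200=1.553, s200=0.025,
                     a_am=12.0, c_am=1.41, s_am=0.14)
        y = (truth["bg"]
             + truth["a200"] * np.exp(-0.5 * ((q - truth["c200"]) / truth["s200"]) ** 2)
             + truth["a_am"] * np.exp(-0.5 * ((q - truth["c_am"]) / truth["s_am"]) ** 2))
        fit = sc.fit_vertical_profile(sc.Profile1D(q=q, intensity=y))
        comp = fit.components["peak200"]
        assert comp["center_q"] == pytest.approx(truth["c200"], abs=1e-6)
        assert comp["sigma_q"] == pytest.approx(truth["s200"], abs=1e-6)
        assert comp["amplitude"] == pytest.approx(truth["a200"], abs=1e-4)
        assert fit.background == pytest.approx(truth["bg"], abs=1e-4)
        assert comp["fwhm_q"] == pytest.approx(
            2 * np.sqrt(2 * np.log(2)) * comp["sigma_q"], rel=1e-12)

    def test_starch_component_only_when_requested(self):
        q = np.arange(1.1, 1.95, 0.005)
        y = 2.0 + 30 * np.exp(-0.5 * ((q - 1.55) / 0.03) ** 2)
        fit3 = sc.fit_vertical_profile(sc.Profile1D(q=q, intensity=y))
        assert "starch" not in fit3.components
        fit4 = sc.fit_vertical_profile(sc.Profile1D(q=q, intensity=y),
                                       include_starch=True)
        assert "starch" in fit4.components

    def test_flat_profile_fits_zero_amplitudes(self):
        q = np.arange(1.1, 1.95, 0.005)
        fit = sc.fit_vertical_profile(
            sc.Profile1D(q=q, intensity=np.full_like(q, 5.0)))
        assert fit.components["peak200"]["amplitude"] == pytest.approx(0.0,
                                                                       abs=1e-6)
        assert fit.background == pytest.approx(5.0, abs=1e-6)


class TestClosedForms:
    def test_d_spacing_identity(self, rng):
        assert sc.d_spacing(2 * np.pi) == pytest.approx(1.0, rel=1e-12)
        for q in rng.uniform(0.2, 3.0, 100):
            assert sc.d_spacing(q) * q == pytest.approx(2 * np.pi, rel=1e-12)
        assert sc.d_spacing(1.55) == pytest.approx(4.054, abs=1e-3)

    def test_scherrer_scaling_and_value(self):
        L1 = sc.scherrer_length(0.05, 0.1, 1.2398)
        L2 = sc.scherrer_length(0.10, 0.1, 1.2398)
        assert L1 == pytest.approx(2 * L2, rel=1e-12)
        assert sc.scherrer_length(1.0, 0.0, 1.0, shape_constant=1.0) == \
            pytest.approx(1.0)
        theta = sc.theta_from_q(1.55, 1.2398)
        assert sc.scherrer_length(0.05, theta, 1.2398) == pytest.approx(
            22.6, abs=0.1)

    def test_scherrer_agrees_with_symbolic_evaluation(self, rng):
        import sympy
        K, lam, beta, theta = sympy.symbols("K lambda beta theta",
                                            positive=True)
        expr = K * lam / (beta * sympy.cos(theta))
        for _ in range(100):
            vals = dict(K=0.9, lam=float(rng.uniform(0.5, 2.0)),
                        beta=float(rng.uniform(0.001, 0.3)),
                        theta=float(rng.uniform(0.0, 1.2)))
            expected = float(expr.subs({K: vals["K"], lam: vals["lam"],
                                        beta: vals["beta"],
                                        theta: vals["theta"]}))
            got = sc.scherrer_length(vals["beta"], vals["theta"], vals["lam"])
            assert got == pytest.approx(expected, rel=1e-10)

    def test_rccc_closed_forms(self):
        chi = np.linspace(0.0, 90.0, 901)
        one = sc.PoleFigure(chi=chi, intensity=np.ones_like(chi))
        assert sc.rccc(one) == pytest.approx(1.0, abs=1e-6)
        const = sc.PoleFigure(chi=chi, intensity=np.full_like(chi, 3.7))
        assert sc.rccc(const) == pytest.approx(3.7, abs=1e-5)

    def test_rccc_matches_refined_grid_oracle(self, rng):
        chi = np.linspace(0.0, 90.0, 91)
        intensity = rng.uniform(0.5, 2.0, 91)
        coarse = sc.rccc(sc.PoleFigure(chi=chi, intensity=intensity))
        fine_chi = np.linspace(0.0, 90.0, 9001)
        fine = sc.rccc(sc.PoleFigure(
            chi=fine_chi, intensity=np.interp(fine_chi, chi, intensity)))
        assert coarse == pytest.approx(fine, abs=1e-4)

    def test_rccc_linear_in_intensity(self, rng):
        chi = np.linspace(0.0, 90.0, 91)
        a = rng.uniform(0.1, 1.0, 91)
        b = rng.uniform(0.1, 1.0, 91)
        assert sc.rccc(sc.PoleFigure(chi=chi, intensity=a + b)) == \
            pytest.approx(sc.rccc(sc.PoleFigure(chi=chi, intensity=a))
                          + sc.rccc(sc.PoleFigure(chi=chi, intensity=b)),
                          rel=1e-10)


class TestPoleFigure:
    def test_rocking_average_is_elementwise_mean(self, rng):
        chi = np.arange(0.5, 30.0, 1.0)
        profiles = [(chi, rng.uniform(1, 5, chi.size)) for _ in range(3)]
        grid, mean = sc.average_rocking_profiles(profiles)
        np.testing.assert_allclose(
            mean, np.mean([p[1] for p in profiles], axis=0))
        consts = [(chi, np.full(chi.size, v)) for v in (1.0, 2.0, 3.0)]
        _, m = sc.average_rocking_profiles(consts)
        np.testing.assert_allclose(m, 2.0)

    def test_stitch_scale_recovery(self):
        chi_r = np.arange(0.5, 30.0, 1.0)
        chi_g = np.arange(15.5, 90.0, 1.0)
        truth = lambda x: 10 * np.exp(-0.5 * (x / 12.0) ** 2) + 1.0
        pole_same = sc.stitch_pole_figure((chi_r, truth(chi_r)),
                                          (chi_g, truth(chi_g)))
        assert pole_same.scale_factor == pytest.approx(1.0, rel=1e-9)
        pole_scaled = sc.stitch_pole_figure((chi_r, truth(chi_r)),
                                            (chi_g, 5.0 * truth(chi_g)))
        assert pole_scaled.scale_factor == pytest.approx(0.2, rel=1e-9)
        np.testing.assert_allclose(pole_scaled.intensity,
                                   truth(pole_scaled.chi), rtol=1e-9)

    def test_disjoint_branches_error(self):
        with pytest.raises(ValueError, match="overlap"):
            sc.stitch_pole_figure((np.array([0.0, 5.0]), np.ones(2)),
                                  (np.array([40.0, 50.0]), np.ones(2)))

    def test_gaussian_fwhm_recovered_and_scales(self):
        chi = np.arange(0.0, 90.5, 1.0)
        for fwhm in (30.0, 15.0):
            sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
            pole = sc.PoleFigure(chi=chi,
                                 intensity=np.exp(-0.5 * (chi / sigma) ** 2))
            got = sc.pole_fwhm(pole)
            assert not got.censored
            assert got.value == pytest.approx(fwhm, abs=0.5)

    def test_constant_profile_is_censored(self):
        chi = np.arange(0.0, 90.5, 1.0)
        pole = sc.PoleFigure(chi=chi, intensity=np.ones_like(chi))
        assert sc.pole_fwhm(pole).censored


class TestEndToEndRecovery:
    def test_peak_center_within_one_bin_and_fwhm_within_2deg(self,
                                                             scatter_noisy):
        spec, giwaxs, rocking = scatter_noisy
        profile = sc.sector_average(giwaxs)
        fit = sc.fit_vertical_profile(profile, fit_window=(1.25, 1.9))
        assert abs(fit.components["peak200"]["center_q"] - 1.55) <= 0.005
        chi_g, i_g = sc.azimuthal_profile(giwaxs)
        high = chi_g >= 15.0
        rock_profiles = []
        for img in rocking:
            cr, ir = sc.azimuthal_profile(img)
            rock_profiles.append((cr[cr <= 30.0], ir[cr <= 30.0]))
        rock = sc.average_rocking_profiles(rock_profiles)
        pole = sc.stitch_pole_figure(rock, (chi_g[high], i_g[high]))
        fwhm = sc.pole_fwhm(pole)
        assert not fwhm.censored
        assert fwhm.value == pytest.approx(30.0, abs=2.0)
        assert pole.scale_factor == pytest.approx(1 / 5.0, rel=0.05)

    def test_scherrer_consistent_with_designed_width(self, scatter_clean):
        spec, giwaxs, _ = scatter_clean
        profile = sc.sector_average(giwaxs)
        fit = sc.fit_vertical_profile(profile, fit_window=(1.25, 1.9))
        comp = fit.components["peak200"]
        # closed-form L from the designed σ_q = 0.03
        fwhm_q = 2 * np.sqrt(2 * np.log(2)) * 0.03
        lam = spec.calibration.wavelength
        beta = (2 * sc.theta_from_q(1.55 + fwhm_q / 2, lam)
                - 2 * sc.theta_from_q(1.55 - fwhm_q / 2, lam))
        theta = sc.theta_from_q(1.55, lam)
        expected = sc.scherrer_length(beta, theta, lam)
        got = sc.scherrer_length(comp["fwhm_2theta_rad"],
                                 sc.theta_from_q(comp["center_q"], lam), lam)
        assert got == pytest.approx(expected, rel=0.1)
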