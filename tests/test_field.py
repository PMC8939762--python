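"""Axisymmetric diffraction propagator and beam metrics."""

import numpy as np
import pytest

from fuskit.exceptions import GridError, InvalidParameterError
from fuskit.field import (
    GridSpec,
    PressureField,
    axial_power_flux,
    beam_metrics,
    max_tumor_pressure,
    on_axis_annuli_closed_form,
    on_axis_piston_closed_form,
    propagate_homogeneous,
    propagate_layered,
)
from fuskit.media import B16F10_TUMOR, MOUSE_SKIN, ULTRASOUND_GEL, Layer, LayeredPath, Medium

from conftest import FREQ_HZ


class TestClosedFormOracle:
    def test_far_field_asymptote(self):
        # Far from the source the disc amplitude falls as k a^2 / (2 z).
        a, k = 1.0, 87.0
        z = 100.0 * a
        assert on_axis_piston_closed_form(a, k, z) == pytest.approx(
            k * a**2 / (2 * z), rel=0.02
        )

    def test_zero_radius_radiates_nothing(self):
        assert on_axis_piston_closed_form(0.0, 87.0, 5.0) == 0.0

    def test_maxima_at_odd_half_wavelength_path_difference(self):
        # |p| peaks at 2 where sqrt(a^2+z^2) - z is an odd multiple of
        # lambda/2 (the sine argument hits pi/2 mod pi).
        a = 1.0
        wavelength = 1480e3 / FREQ_HZ
        k = 2 * np.pi / wavelength
        for m in (1, 3, 5):
            delta = m * wavelength / 2.0
            z = (a**2 - delta**2) / (2 * delta)
            assert on_axis_piston_closed_form(a, k, z) == pytest.approx(2.0, abs=1e-9)

    def test_propagator_matches_disc_oracle_within_1pct(self, disc_vs_closed_form):
        fld, closed, _, _ = disc_vs_closed_form
        err = np.max(np.abs(fld.on_axis() - closed)) / closed.max()
        assert err < 0.01

    def test_propagator_matches_annuli_closed_form(self, water_field, lens_design,
                                                   lossless_water):
        k = lossless_water.wavenumber_per_mm(FREQ_HZ).real
        closed = np.abs(
            on_axis_annuli_closed_form(lens_design.transmit_annuli_mm, k,
                                       water_field.z_mm)
        )
        err = np.max(np.abs(water_field.on_axis() - closed)) / closed.max()
        assert err < 0.01

    def test_rayleigh_quadrature_agrees_with_spectrum(self, lens_design,
                                                      lossless_water):
        grid = GridSpec(r_max_mm=0.12, dr_mm=0.012, z_min_mm=4.5, z_max_mm=5.5,
                        dz_mm=0.05)
        annuli = lens_design.transmit_annuli_mm
        asm = propagate_homogeneous(annuli, lossless_water, grid, FREQ_HZ)
        ray = propagate_homogeneous(annuli, lossless_water, grid, FREQ_HZ,
                                    method="rayleigh")
        scale = np.abs(asm.p).max()
        assert np.max(np.abs(np.abs(asm.p) - np.abs(ray.p))) / scale < 0.01


class TestHomogeneousField:
    def test_focus_forms_near_design_focal_length(self, water_field):
        metrics = beam_metrics(water_field)
        assert metrics.focal_length_mm == pytest.approx(5.0, rel=0.03)

    def test_focal_diameter_and_depth(self, water_field):
        metrics = beam_metrics(water_field)
        assert metrics.focal_diameter_um == pytest.approx(96.0, rel=0.10)
        assert metrics.focal_depth_um == pytest.approx(790.0, rel=0.15)

    def test_all_blocked_aperture_is_silent(self, lossless_water):
        grid = GridSpec(r_max_mm=0.1, dr_mm=0.01, z_min_mm=4.0, z_max_mm=6.0,
                        dz_mm=0.1)
        with pytest.warns(UserWarning, match="zero field"):
            fld = propagate_homogeneous([], lossless_water, grid, FREQ_HZ)
        assert np.all(fld.p == 0)

    def test_coarse_grid_refused(self, lossless_water):
        wavelength = lossless_water.wavelength_mm(FREQ_HZ)
        grid = GridSpec(dr_mm=wavelength / 2.0)
        with pytest.raises(GridError, match="lambda/4"):
            propagate_homogeneous([(0.0, 1.0)], lossless_water, grid, FREQ_HZ)

    def test_fresnel_gain_over_unmasked_disc(self, water_field, lens_design,
                                             lossless_water):
        # Blocking the out-of-phase zones must beat the full open disc.
        grid = GridSpec(r_max_mm=0.05, dr_mm=0.01, z_min_mm=4.5, z_max_mm=5.5,
                        dz_mm=0.02)
        full = propagate_homogeneous(
            [(0.0, lens_design.aperture_radius_mm)], lossless_water, grid, FREQ_HZ
        )
        assert water_field.on_axis().max() > np.abs(full.p).max()

    def test_energy_conservation_lossless(self, lens_design, lossless_water):
        flux = axial_power_flux(
            lens_design.transmit_annuli_mm, lossless_water, [1.0, 3.0, 5.0], FREQ_HZ
        )
        assert np.ptp(flux) / flux.mean() < 0.02

    def test_normalized_field_peaks_at_one(self, water_field):
        assert np.abs(water_field.normalized().p).max() == pytest.approx(1.0)


class TestBeamMetrics:
    def test_gaussian_beam_fwhm_closed_form(self):
        # Half-amplitude convention on a separable Gaussian recovers
        # FWHM = 2*sqrt(2 ln 2) * sigma on both axes.
        sigma_r, sigma_z, z0 = 0.05, 0.4, 5.0
        r = np.linspace(0, 0.3, 301)
        z = np.linspace(3.0, 7.0, 801)
        p = np.exp(-(r[:, None] ** 2) / (2 * sigma_r**2)) * np.exp(
            -((z[None, :] - z0) ** 2) / (2 * sigma_z**2)
        )
        fld = PressureField(r, z, p.astype(complex), FREQ_HZ, "synthetic")
        m = beam_metrics(fld, width_convention="half_amplitude")
        fwhm = 2 * np.sqrt(2 * np.log(2))
        assert m.focal_diameter_um == pytest.approx(fwhm * sigma_r * 1e3, rel=1e-3)
        assert m.focal_depth_um == pytest.approx(fwhm * sigma_z * 1e3, rel=1e-3)
        assert m.focal_length_mm == pytest.approx(z0, abs=1e-6)

    def test_unbracketed_half_max_names_axis(self):
        r = np.linspace(0, 0.05, 21)
        z = np.linspace(4.0, 6.0, 101)
        p = np.exp(-((z[None, :] - 5.0) ** 2)) * np.exp(
            -(r[:, None] ** 2) / (2 * 10.0**2)  # much wider than the grid
        )
        fld = PressureField(r, z, p.astype(complex), FREQ_HZ, "synthetic")
        with pytest.raises(InvalidParameterError, match="lateral"):
            beam_metrics(fld)


class TestLayeredField:
    def test_reduces_to_homogeneous_without_contrast(self, lens_design,
                                                     lossless_water):
        grid = GridSpec(r_max_mm=0.1, dr_mm=0.01, z_min_mm=4.5, z_max_mm=5.5,
                        dz_mm=0.02)
        annuli = lens_design.transmit_annuli_mm
        hom = propagate_homogeneous(annuli, lossless_water, grid, FREQ_HZ)
        path = LayeredPath(
            layers=(Layer(lossless_water, 2.0), Layer(lossless_water, 1.0)),
            terminal=lossless_water,
        )
        lay = propagate_layered(annuli, path, grid, FREQ_HZ, calibration_pa=1.0)
        assert np.allclose(
            np.abs(lay.normalized().p), np.abs(hom.normalized().p), atol=1e-9
        )

    def test_attenuation_only_oracle_at_tumor_boundary(self, lens_design):
        # With the focus at the gel/skin/tumor-stack boundary, the peak is
        # the free-field calibration reduced by the extra skin attenuation:
        # p ~ 4.53 MPa * exp(-(alpha_skin - alpha_gel) * t_skin).
        annuli = lens_design.transmit_annuli_mm
        t_skin = 0.4
        expected = 4.53e6 * np.exp(
            -(MOUSE_SKIN.attenuation_np_mm - ULTRASOUND_GEL.attenuation_np_mm)
            * t_skin
        )
        peaks, mx, _ = max_tumor_pressure(annuli, t_skin, [4.6])
        assert mx == pytest.approx(expected, rel=0.10)

    def test_six_distance_sweep_spans_printed_range(self, lens_design):
        peaks, mx, mn = max_tumor_pressure(
            lens_design.transmit_annuli_mm, 0.4, [3.1, 3.4, 3.7, 4.0, 4.3, 4.6]
        )
        assert mx / 1e6 == pytest.approx(3.0, rel=0.10)
        assert mn / 1e6 == pytest.approx(2.1, rel=0.10)
        assert np.all(np.diff(peaks) > 0)  # farther standoff -> focus shallower in tumor

    def test_thicker_skin_strictly_reduces_pressure(self, lens_design):
        annuli = lens_design.transmit_annuli_mm
        maxima = [
            max_tumor_pressure(annuli, t, [3.7, 4.6])[1] for t in (0.4, 0.9, 1.5)
        ]
        assert maxima[0] > maxima[1] > maxima[2]

    def test_calibration_linearity(self, lens_design):
        annuli = lens_design.transmit_annuli_mm
        path = LayeredPath.gel_skin_tumor(4.0, 0.4)
        grid = GridSpec(r_max_mm=0.05, dr_mm=0.01, z_min_mm=4.4, z_max_mm=5.6,
                        dz_mm=0.05)
        one = propagate_layered(annuli, path, grid, FREQ_HZ, calibration_pa=1e6)
        two = propagate_layered(annuli, path, grid, FREQ_HZ, calibration_pa=2e6)
        assert np.allclose(np.abs(two.p), 2 * np.abs(one.p), rtol=1e-12)

    def test_higher_attenuation_never_increases_peak(self, lens_design):
        annuli = lens_design.transmit_annuli_mm
        lossy_tumor = Medium("tumor_lossy", 1060.0, 1521.0,
                             B16F10_TUMOR.attenuation_np_mm * 3)

        def factory(gel_span, skin_t, tumor=lossy_tumor):
            return LayeredPath(
                layers=(Layer(ULTRASOUND_GEL, gel_span), Layer(MOUSE_SKIN, skin_t)),
                terminal=tumor,
            )

        base = max_tumor_pressure(annuli, 0.4, [3.4])[1]
        lossy = max_tumor_pressure(annuli, 0.4, [3.4], path_factory=factory)[1]
        assert lossy < base

    def test_negative_thickness_rejected(self, lossless_water):
        with pytest.raises(InvalidParameterError):
            LayeredPath(layers=(Layer(lossless_water, -1.0),),
                        terminal=lossless_water)


class TestFieldIO:
    def test_hdf5_roundtrip(self, tmp_path, water_field):
        path = tmp_path / "field.h5"
        water_field.save_hdf5(path)
        restored = PressureField.load_hdf5(path)
        assert np.array_equal(restored.p, water_field.p)
        assert np.array_equal(restored.r_mm, water_field.r_mm)
        assert restored.method == water_field.method
        assert restored.metadata["medium"] == "water_lossless"
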