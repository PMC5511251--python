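import numpy as np
import pytest

from fiberdiff import (
    AnalysisError,
    AzimuthalProfile,
    InputError,
    Profile1D,
    azimuthal_profile,
    coherence_length,
    estimate_background,
    fit_gaussian_peaks,
    gen_pattern,
    gen_powder,
    gen_profile,
    merge_profiles,
    mutual_orientation,
    sector_integrate,
)
from fiberdiff.profiles import PeakFit


class TestBackground:
    def test_constant_profile(self):
        q = np.linspace(0.1, 0.5, 60)
        prof = Profile1D(q=q, intensity=np.full(60, 3.5))
        bg = estimate_background(prof, degree=2)
        np.testing.assert_allclose(bg.evaluate(q), 3.5, rtol=1e-9)
        np.testing.assert_allclose(prof.intensity - bg.evaluate_clipped(prof), 0.0, atol=1e-9)

    def test_ramp_recovery(self):
        q = np.linspace(0.3, 1.0, 400)
        prof = Profile1D(
            q=q, intensity=2.0 + 1.5 * q + 5 * np.exp(-0.5 * ((q - 0.63) / 0.02) ** 2)
        )
        bg = estimate_background(prof, degree=1, smooth_window=5)
        assert bg.coefficients[0] == pytest.approx(2.0, rel=0.02)
        assert bg.coefficients[1] == pytest.approx(1.5, rel=0.02)

    def test_anchor_interpolation(self):
        # two peaks -> 3 anchors (endpoints + one inter-peak minimum);
        # degree 2 = anchors - 1 makes the fit an exact interpolation
        q = np.linspace(0.3, 1.6, 500)
        I = (
            1.0
            + 4 * np.exp(-0.5 * ((q - 0.63) / 0.05) ** 2)
            + 3 * np.exp(-0.5 * ((q - 1.34) / 0.05) ** 2)
        )
        prof = Profile1D(q=q, intensity=I)
        bg = estimate_background(prof, degree=2, smooth_window=5)
        resid_at_anchors = bg.anchor_intensity - bg.evaluate(bg.anchor_q)
        np.testing.assert_allclose(resid_at_anchors, 0.0, atol=1e-8)

    def test_degree_reduction_recorded(self):
        q = np.linspace(0.1, 0.5, 50)
        prof = Profile1D(q=q, intensity=1.0 + q)  # monotone: only 2 anchors
        bg = estimate_background(prof, degree=4)
        assert bg.degree_used < bg.degree_requested
        assert bg.degree_used == 1

    def test_clipping_never_exceeds_intensity(self):
        prof, _ = gen_powder([10, 4.7], [0.07, 0.07], [5, 4], noise_fraction=0.05, seed=1)
        bg = estimate_background(prof, degree=4)
        assert np.all(bg.evaluate_clipped(prof) <= prof.intensity + 1e-12)


class TestGaussianPeaks:
    def test_single_gaussian_recovery(self):
        q = np.linspace(0.3, 1.0, 400)
        prof = Profile1D(
            q=q, intensity=0.5 + 4 * np.exp(-0.5 * ((q - 0.63) / 0.02) ** 2)
        )
        bg = estimate_background(prof, degree=1)
        peaks = fit_gaussian_peaks(prof, 1, bg)
        assert peaks[0].center == pytest.approx(0.63, rel=0.005)
        assert peaks[0].width_sigma == pytest.approx(0.02, rel=0.05)

    def test_powder_fixture_spacings(self):
        sigma = 0.18 / np.sqrt(2 * np.pi)
        prof, _ = gen_powder([10.0, 4.7], [sigma, sigma], [5.0, 4.0])
        bg = estimate_background(prof, degree=3)
        peaks = fit_gaussian_peaks(prof, 2, bg)
        ds = sorted(p.d_spacing for p in peaks)
        assert ds[0] == pytest.approx(4.7, rel=0.02)
        assert ds[1] == pytest.approx(10.0, rel=0.02)

    def test_pure_noise_flagged_or_fails(self):
        rng = np.random.default_rng(7)
        q = np.linspace(0.3, 1.0, 300)
        prof = Profile1D(q=q, intensity=np.abs(rng.standard_normal(300)) * 0.01 + 1.0)
        bg = estimate_background(prof, degree=2)
        try:
            peaks = fit_gaussian_peaks(prof, 1, bg)
        except AnalysisError:
            return
        assert peaks[0].low_signal or peaks[0].height < 0.1

    def test_derived_fields_consistent(self):
        pk = PeakFit(center=0.63, height=4.0, width_sigma=0.02)
        assert pk.integral_width == pytest.approx(pk.integral_intensity / pk.height, rel=1e-9)
        assert pk.d_spacing == pytest.approx(2 * np.pi / 0.63, rel=1e-12)

    def test_bad_n_peaks(self, simple_profile):
        with pytest.raises(InputError):
            fit_gaussian_peaks(simple_profile, 0)
        with pytest.raises(InputError):
            fit_gaussian_peaks(simple_profile, 7)


class TestCoherenceLength:
    def test_inverse_definition(self):
        pk = PeakFit(center=0.63, height=1.0, width_sigma=(2 * np.pi / 35) / np.sqrt(2 * np.pi))
        assert coherence_length(pk) == pytest.approx(35.0, rel=1e-9)

    @pytest.mark.parametrize("width,expected", [(0.157, 40.02), (0.209, 30.06)])
    def test_paper_range_endpoints(self, width, expected):
        pk = PeakFit(center=0.63, height=1.0, width_sigma=width / np.sqrt(2 * np.pi))
        assert coherence_length(pk) == pytest.approx(expected, abs=0.05)

    def test_resolution_limited(self):
        pk = PeakFit(center=0.63, height=1.0, width_sigma=1e-14)
        with pytest.warns(UserWarning, match="resolution"):
            assert coherence_length(pk) == np.inf


class TestSectorIntegration:
    def test_isotropic_equator_equals_meridian(self, wt_model):
        from fiberdiff import default_geometry

        pat, _ = gen_pattern(
            wt_model, [(90.0, 1e6, 1.0)], default_geometry(129), seed=0, shape=(129, 129)
        )
        eq = sector_integrate(pat, 90.0, 10.0)
        me = sector_integrate(pat, 0.0, 10.0)
        common = np.linspace(max(eq.q[0], me.q[0]), min(eq.q[-1], me.q[-1]), 150)
        a, b = eq.interp_at(common), me.interp_at(common)
        assert np.sqrt(np.mean((a - b) ** 2)) / a.mean() < 0.01

    def test_equatorial_only_pattern(self, wt_model):
        from fiberdiff import default_geometry

        pat, _ = gen_pattern(
            wt_model,
            [(90.0, 5.0, 1.0)],
            default_geometry(129),
            seed=0,
            shape=(129, 129),
            background_coeffs=(0.001,),
        )
        eq = sector_integrate(pat, 90.0, 10.0)
        me = sector_integrate(pat, 0.0, 10.0)
        band = (0.035, 0.055)
        eq_peak = eq.intensity[(eq.q > band[0]) & (eq.q < band[1])].max()
        me_peak = me.intensity[(me.q > band[0]) & (me.q < band[1])].max()
        assert me_peak < 0.05 * eq_peak  # meridian stays near background

    def test_pinhole_single_pixel(self, geometry):
        values = np.zeros((65, 65))
        geometry = type(geometry)(
            wavelength=4.5, distance=1000.0, pixel_size=2.0, beam_center=(32.0, 32.0)
        )
        values[32, 52] = 100.0  # 20 px right of center: on the equator
        from fiberdiff import Pattern2D

        pat = Pattern2D(values=values, geometry=geometry)
        prof = sector_integrate(pat, 90.0, 10.0)
        rho = 20 * 2.0
        q_hand = 4 * np.pi / 4.5 * np.sin(0.5 * np.arctan(rho / 1000.0))
        bright = prof.q[np.argmax(prof.intensity)]
        assert bright == pytest.approx(q_hand, abs=(prof.q[1] - prof.q[0]))

    def test_flux_conservation_isotropic(self, wt_model):
        from fiberdiff import default_geometry

        pat, _ = gen_pattern(
            wt_model, [(90.0, 1e6, 1.0)], default_geometry(129), seed=0, shape=(129, 129)
        )
        eq = sector_integrate(pat, 90.0, 10.0)
        me = sector_integrate(pat, 0.0, 10.0)
        lo = max(eq.q[0], me.q[0])
        hi = min(eq.q[-1], me.q[-1])
        grid = np.linspace(lo, hi, 300)
        tot_eq = np.trapezoid(eq.interp_at(grid), grid)
        tot_me = np.trapezoid(me.interp_at(grid), grid)
        assert tot_eq == pytest.approx(tot_me, rel=0.02)

    def test_empty_sector_error(self, geometry):
        from fiberdiff import Pattern2D

        pat = Pattern2D(values=np.ones((5, 5)), geometry=geometry)
        with pytest.raises(InputError):
            sector_integrate(pat, 90.0, opening=200.0)


class TestAzimuthalProfile:
    def test_isotropic_flat(self, wt_model):
        from fiberdiff import default_geometry

        pat, _ = gen_pattern(
            wt_model, [(90.0, 1e6, 1.0)], default_geometry(129), seed=0, shape=(129, 129)
        )
        az = azimuthal_profile(pat, (0.03, 0.06))
        cv = az.intensity.std() / az.intensity.mean()
        assert cv < 0.02

    def test_single_population_maximum(self, wt_model, geometry):
        pat, _ = gen_pattern(wt_model, [(90.0, 10.0, 1.0)], geometry, seed=0)
        az = azimuthal_profile(pat, (0.035, 0.055))
        peak_phi = az.phi[np.argmax(az.intensity)]
        folded = min(peak_phi % 180, 180 - peak_phi % 180 + 90)
        assert abs((peak_phi % 180) - 90.0) <= 2.0

    def test_two_population_two_maxima(self, wt_model, geometry, scenarios):
        pat, _ = gen_pattern(
            wt_model, scenarios["WT"].orientations, geometry, seed=0
        )
        az = azimuthal_profile(pat, (0.035, 0.055))
        phi = np.mod(az.phi, 180.0)
        order = np.argsort(phi)
        phi, inten = phi[order], az.intensity[order]
        interior = np.arange(1, len(phi) - 1)
        is_max = (inten[interior] > inten[interior - 1]) & (
            inten[interior] > inten[interior + 1]
        )
        assert is_max.sum() >= 2

    def test_empty_band_error(self, wt_model, geometry):
        pat, _ = gen_pattern(wt_model, [(90.0, 10.0, 1.0)], geometry, seed=0)
        with pytest.raises((AnalysisError, InputError)):
            azimuthal_profile(pat, (50.0, 60.0))


class TestMutualOrientation:
    def test_wt_tilt(self, wt_model, geometry, scenarios):
        pat, _ = gen_pattern(wt_model, scenarios["WT"].orientations, geometry, seed=0)
        az = azimuthal_profile(pat, (0.035, 0.055))
        res = mutual_orientation(az)
        assert res.separation == pytest.approx(31.0, abs=1.0)

    def test_crisscross_tilt(self, geometry, scenarios):
        sc = scenarios["WT_A2V"]
        pat, _ = gen_pattern(
            None, sc.orientations, geometry, seed=0, components=sc.components
        )
        az = azimuthal_profile(pat, (0.035, 0.055))
        res = mutual_orientation(az)
        assert res.separation == pytest.approx(27.0, abs=1.0)

    def test_single_arc_no_separation(self, a2v_model, geometry):
        pat, _ = gen_pattern(a2v_model, [(90.0, 6.0, 1.0)], geometry, seed=0)
        az = azimuthal_profile(pat, (0.06, 0.09))
        res = mutual_orientation(az)
        assert res.separation is None
        assert len(res.peak_centers) == 1

    def test_rotation_invariance(self, wt_model, geometry, scenarios):
        # rotating the pattern and the declared axis together changes nothing
        pat0, _ = gen_pattern(
            wt_model, scenarios["WT"].orientations, geometry, seed=0
        )
        pat45, _ = gen_pattern(
            wt_model,
            scenarios["WT"].orientations,
            geometry,
            seed=0,
            axis_direction=45.0,
        )
        res0 = mutual_orientation(azimuthal_profile(pat0, (0.035, 0.055)))
        res45 = mutual_orientation(azimuthal_profile(pat45, (0.035, 0.055)))
        assert res45.separation == pytest.approx(res0.separation, abs=0.5)


class TestMerge:
    def test_scaled_copy(self, simple_profile):
        tripled = Profile1D(
            q=simple_profile.q, intensity=3.0 * simple_profile.intensity
        )
        merged = merge_profiles([simple_profile, tripled])
        np.testing.assert_allclose(merged.intensity, simple_profile.intensity, rtol=1e-6)

    def test_three_ranges_reproduce_mother(self, wt_model):
        mother, _ = gen_profile(wt_model, q_grid=np.linspace(0.005, 0.25, 900))
        parts = []
        for lo, hi, s in [(0.005, 0.06, 1.0), (0.04, 0.15, 5.0), (0.12, 0.25, 0.3)]:
            m = (mother.q >= lo) & (mother.q <= hi)
            parts.append(Profile1D(q=mother.q[m], intensity=s * mother.intensity[m]))
        merged = merge_profiles(parts)
        rel = np.abs(merged.interp_at(mother.q) - mother.intensity) / mother.intensity.max()
        assert np.sqrt(np.mean(rel**2)) < 0.005

    def test_disjoint_ranges_error(self):
        a = Profile1D(q=[0.01, 0.02, 0.03], intensity=[1, 1, 1])
        b = Profile1D(q=[0.2, 0.3, 0.4], intensity=[1, 1, 1])
        with pytest.raises(InputError):
            merge_profiles([a, b])

    def test_needs_two(self, simple_profile):
        with pytest.raises(InputError):
            merge_profiles([simple_profile])
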