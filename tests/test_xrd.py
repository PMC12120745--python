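import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import voigt_profile

from spinescan.geometry import BeamGeometry
from spinescan.synthetic import BonePhantom, NOISELESS, chord_mineral, default_scan, simulate_frame
from spinescan.xrd import (
    RadialProfile,
    bragg_d,
    fit_voigt,
    integrate_azimuthal,
    reduce_point,
    subtract_background,
    two_theta_of_c,
)


def _profile(x, y, n_px=100):
    return RadialProfile(x, y, np.full(x.size, n_px))


class TestIntegration:
    def test_uniform_frame_gives_flat_profile(self, beam):
        from spinescan.xrd import DetectorFrame

        fr = DetectorFrame(np.full(beam.detector_shape_px, 7.0), beam)
        prof = integrate_azimuthal(fr, solid_angle=False)
        good = prof.n_pixels > 0
        cv = prof.intensity[good].std() / prof.intensity[good].mean()
        assert cv < 0.02

    def test_empty_sector_flagged_not_raised(self, center_frame_noiseless):
        # a 2theta window beyond the detector corner has no pixels
        prof = integrate_azimuthal(center_frame_noiseless, (30.0, 31.0))
        assert prof.empty

    def test_sector_integration_restricts_azimuth(self, center_frame_noiseless):
        # textured frame: the lobe sector is brighter than its orthogonal one
        lobe = integrate_azimuthal(center_frame_noiseless, chi_range=(85, 105))
        ortho = integrate_azimuthal(center_frame_noiseless, chi_range=(-5, 15))
        assert np.nanmax(lobe.intensity) > 2 * np.nanmax(ortho.intensity)


class TestBackground:
    def test_pure_ramp_removed(self):
        x = np.linspace(10, 13, 400)
        prof = _profile(x, 3.0 * x + 7.0)
        out = subtract_background(prof, (11.0, 12.0))
        assert np.allclose(out.intensity, 0.0, atol=1e-9)

    def test_ramp_plus_voigt_recovers_peak_area(self):
        """Near-Gaussian peak: window integral of the residual returns the
        injected area within 1%. With heavy Lorentzian tails part of the
        peak leaks into the flanks and the recovery degrades gracefully."""
        x = np.linspace(9.5, 13.5, 4000)
        dx = x[1] - x[0]
        area = 42.0
        sel = (x >= 11.0) & (x < 12.0)

        y = 2.0 * x + 1.0 + area * voigt_profile(x - 11.5, 0.06, 0.005)
        out = subtract_background(_profile(x, y), (11.0, 12.0))
        assert out.intensity[sel].sum() * dx == pytest.approx(area, rel=0.01)

        y_tail = 2.0 * x + 1.0 + area * voigt_profile(x - 11.5, 0.08, 0.05)
        out_tail = subtract_background(_profile(x, y_tail), (11.0, 12.0))
        assert out_tail.intensity[sel].sum() * dx == pytest.approx(area, rel=0.10)

    def test_window_without_flanks_raises(self):
        x = np.linspace(11.1, 11.9, 100)
        with pytest.raises(ValueError):
            subtract_background(_profile(x, np.ones_like(x)), (11.0, 12.0))


class TestVoigtFit:
    def test_noiseless_voigt_recovered_to_a_tenth_percent(self):
        x = np.linspace(10.5, 12.5, 1500)
        y = 120.0 * voigt_profile(x - 11.49, 0.03, 0.02) + 5.0 + 0.3 * x
        fit = fit_voigt(_profile(x, y), fit_window=(11.0, 12.0))
        assert fit.ok
        assert fit.center_2theta_deg == pytest.approx(11.49, rel=1e-3)
        assert fit.gaussian_sigma == pytest.approx(0.03, rel=1e-3)
        assert fit.lorentzian_gamma == pytest.approx(0.02, rel=1e-3)
        assert fit.amplitude == pytest.approx(120.0, rel=1e-3)

    def test_pure_gaussian_limit(self):
        x = np.linspace(10.5, 12.5, 1500)
        sigma = 0.06
        y = 50.0 * np.exp(-0.5 * ((x - 11.6) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        fit = fit_voigt(_profile(x, y), fit_window=(11.1, 12.1))
        assert fit.ok
        assert fit.lorentzian_gamma <= 1e-3
        assert fit.center_2theta_deg == pytest.approx(11.6, abs=1e-4)

    def test_flat_noise_yields_not_ok(self):
        rng = np.random.default_rng(0)
        x = np.linspace(10.5, 12.5, 800)
        fit = fit_voigt(_profile(x, rng.normal(10, 1, x.size)), fit_window=(11.0, 12.0))
        assert not fit.ok

    def test_fit_matches_grid_search_oracle_on_random_peaks(self):
        """Independent oracle: dense center grid, widths fixed at truth,
        amplitude/background solved linearly; fit center within one bin."""
        rng = np.random.default_rng(42)
        x = np.linspace(10.5, 12.5, 1000)
        bin_w = x[1] - x[0]
        for _ in range(20):
            c = rng.uniform(11.2, 11.8)
            sig = rng.uniform(0.02, 0.12)
            gam = rng.uniform(0.01, 0.08)
            amp = rng.uniform(30, 200)
            b0, b1 = rng.uniform(0, 20), rng.uniform(-2, 2)
            y = amp * voigt_profile(x - c, sig, gam) + b0 + b1 * x
            y += rng.normal(0, 0.02 * amp * voigt_profile(0, sig, gam), x.size)

            centers = np.arange(11.1, 11.9, bin_w / 4)
            best, best_sse = None, np.inf
            for cc in centers:
                basis = np.column_stack(
                    [voigt_profile(x - cc, sig, gam), np.ones_like(x), x]
                )
                coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
                sse = ((basis @ coef - y) ** 2).sum()
                if sse < best_sse:
                    best, best_sse = cc, sse
            fit = fit_voigt(_profile(x, y), fit_window=(11.0, 12.0))
            assert fit.ok
            assert abs(fit.center_2theta_deg - best) <= bin_w


class TestBragg:
    def test_apatite_ring_at_18kev(self, beam):
        c, d002 = bragg_d(11.49175, beam)
        assert d002 == pytest.approx(3.440, abs=2e-3)
        assert c == pytest.approx(6.880, abs=4e-3)

    def test_backscattering_limit(self):
        beam = BeamGeometry(energy_keV=18.0)
        c, d002 = bragg_d(180.0, beam)
        assert d002 == pytest.approx(beam.wavelength_A / 2)

    def test_printed_two_theta_window_brackets_apatite(self, beam):
        c_hi, _ = bragg_d(11.4, beam)
        c_lo, _ = bragg_d(11.7, beam)
        assert c_lo < 6.88 < c_hi
        assert c_lo == pytest.approx(6.757, abs=2e-3)
        assert c_hi == pytest.approx(6.934, abs=2e-3)

    def test_non_physical_angle_rejected(self, beam):
        for bad in (0.0, -5.0, 181.0):
            with pytest.raises(ValueError):
                bragg_d(bad, beam)

    @given(st.floats(min_value=5.0, max_value=175.0),
           st.floats(min_value=5.0, max_value=174.0))
    @settings(deadline=None, max_examples=50)
    def test_bragg_d_strictly_decreasing_in_angle(self, a, b):
        beam = BeamGeometry()
        lo, hi = sorted((a, b))
        if hi - lo < 1e-6:
            return
        assert bragg_d(hi, beam)[0] < bragg_d(lo, beam)[0]

    @given(st.floats(min_value=6.0, max_value=40.0))
    @settings(deadline=None, max_examples=50)
    def test_wavelength_scaling_doubles_sin_theta(self, two_theta):
        """At fixed d, doubling λ doubles sin θ (below the Bragg limit)."""
        b1 = BeamGeometry(energy_keV=18.0)
        b2 = BeamGeometry(energy_keV=9.0)  # doubled wavelength
        d1 = bragg_d(two_theta, b1)[1]
        sin1 = b1.wavelength_A / (2 * d1)
        sin2 = b2.wavelength_A / (2 * d1)
        assert sin2 == pytest.approx(2 * sin1, rel=1e-12)


class TestReducePoint:
    def test_round_trip_accuracy_across_chords(self, phantom, beam):
        """Noiseless simulate → reduce recovers the path-mean d to <2e-4."""
        scan = default_scan(radius_um=phantom.radius_um)
        for b in (0.0, 6.0, 12.0, 18.0, 21.0):
            fr = simulate_frame(phantom, b, 0.0, beam, scan, NOISELESS)
            _, d_true = chord_mineral(phantom, b, scan.beam_size_um)
            pt = reduce_point(fr)
            assert pt.valid
            assert abs(pt.d_A - d_true) / d_true < 2e-4
            assert pt.d002_A == pytest.approx(pt.d_A / 2)

    def test_beam_miss_gives_invalid_point(self, phantom, beam):
        fr = simulate_frame(phantom, 35.0, 0.0, beam, None, NOISELESS)
        pt = reduce_point(fr)
        assert not pt.valid
        assert np.isnan(pt.d_A)

    def test_edge_chord_compressed_relative_to_center(self, phantom, beam):
        scan = default_scan(radius_um=phantom.radius_um)
        fr_c = simulate_frame(phantom, 0.0, 0.0, beam, scan, NOISELESS)
        fr_e = simulate_frame(phantom, 20.0, 0.0, beam, scan, NOISELESS)
        d_c = reduce_point(fr_c).d_A
        d_e = reduce_point(fr_e).d_A
        assert d_e < d_c
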