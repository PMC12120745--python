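import numpy as np
import pytest

from spinescan.sinogram import Sinogram
from spinescan.synthetic import BonePhantom, NOISELESS, default_scan, simulate_scan
from spinescan.tomo import (
    apply_shifts,
    backproject,
    DriftModel,
    estimate_drift,
    normalize_background,
)
from spinescan.xrf import ElementWindow, build_maps


def _disk_sinogram(n_x=31, n_omega=12, radius=10.0, shifts=None, noise_rng=None,
                   counts=2500.0):
    """Analytic Sr-like sinogram of a centered disk with optional per-angle
    shifts (in x-steps) and Poisson noise."""
    x = np.arange(n_x) - (n_x - 1) / 2.0
    omega = np.linspace(5, 175, n_omega)
    shifts = np.zeros(n_omega) if shifts is None else np.asarray(shifts, float)
    vals = np.zeros((n_omega, n_x))
    for i, s in enumerate(shifts):
        vals[i] = counts * np.sqrt(np.maximum(radius**2 - (x - s) ** 2, 0.0)) / radius
    if noise_rng is not None:
        vals = noise_rng.poisson(vals).astype(float)
    return Sinogram(vals, omega, x, quantity="Sr")


class TestDrift:
    def test_integer_shifts_recovered_exactly(self):
        inj = np.array([-2, -1, 0, 1, 2, -2, 0, 2, 1, -1, 0, 1], dtype=float)
        sino = _disk_sinogram(shifts=inj)
        drift = estimate_drift(sino)
        assert np.allclose(drift.shifts_px, inj, atol=1e-9)

    def test_zero_drift_estimates_near_zero(self):
        rng = np.random.default_rng(3)
        sino = _disk_sinogram(noise_rng=rng)
        drift = estimate_drift(sino)
        assert np.all(np.abs(drift.shifts_px) < 0.1)

    def test_fractional_shifts_recovered_at_default_snr(self):
        rng = np.random.default_rng(11)
        inj = rng.uniform(-2, 2, 12)
        sino = _disk_sinogram(shifts=inj, noise_rng=rng)
        drift = estimate_drift(sino)
        assert np.max(np.abs(drift.shifts_px - inj)) <= 0.3

    def test_fractional_shifts_on_simulated_scan(self, dataset_noisy):
        """End-to-end: Sr sinogram from simulated spectra, injected stage
        drift recovered to ≤0.3 px at the default counting statistics."""
        maps = build_maps(dataset_noisy, {"Sr": ElementWindow.default("Sr")},
                          elastic=False)
        drift = estimate_drift(maps["Sr"])
        inj = np.asarray(dataset_noisy.truth["drift_px"])
        assert np.max(np.abs(drift.shifts_px - inj)) <= 0.3

    def test_weak_rows_interpolated_and_flagged(self):
        inj = np.linspace(-1.5, 1.5, 12)
        sino = _disk_sinogram(shifts=inj)
        sino.values[5] = 0.01  # dead-detector row
        drift = estimate_drift(sino)
        assert drift.interpolated[5]
        assert abs(drift.shifts_px[5] - inj[5]) < 0.5


class TestApplyShifts:
    def test_apply_then_inverse_recovers_original(self):
        sino = _disk_sinogram()
        drift = DriftModel(np.full(sino.n_omega, 0.6), reference_center=15.0)
        back = DriftModel(np.full(sino.n_omega, -0.6), reference_center=15.0)
        round_trip = apply_shifts(apply_shifts(sino, drift), back)
        inner = round_trip.mask
        # linear interpolation smooths the sharp disk edge; interior cells
        # (away from the edge kink) come back essentially unchanged
        err = np.abs(round_trip.values - sino.values)
        assert np.nanmax(err[inner]) < 0.15 * sino.values.max()
        flat = inner & (np.abs(sino.x_um)[None, :] < 5.0)
        assert np.nanmax(err[flat]) < 0.02 * sino.values.max()

    def test_masked_cells_stay_masked(self):
        sino = _disk_sinogram()
        sino.mask[2, 10] = False
        out = apply_shifts(sino, DriftModel(np.full(sino.n_omega, 1.0), 15.0))
        # the invalid cell moves with the shift: x index 9 now poisoned
        assert not out.mask[2, 9]

    def test_integer_mode_is_exact(self):
        sino = _disk_sinogram()
        drift = DriftModel(np.full(sino.n_omega, 2.0), 15.0)
        out = apply_shifts(sino, drift, mode="integer")
        assert np.allclose(out.values[0, :-2], sino.values[0, 2:])

    def test_shift_equivariance_reduces_column_spread(self):
        """Estimate→apply on drifted data reduces per-column center-of-mass
        variance across angles by ≥90% (noiseless)."""
        rng = np.random.default_rng(5)
        inj = rng.uniform(-2, 2, 12)
        sino = _disk_sinogram(shifts=inj)
        corrected = apply_shifts(sino, estimate_drift(sino))

        def com_spread(s):
            coms = []
            for i in range(s.n_omega):
                v = np.where(s.mask[i], s.values[i], 0.0)
                coms.append((v * s.x_um).sum() / v.sum())
            return np.var(coms)

        assert com_spread(corrected) <= 0.1 * com_spread(sino)


class TestNormalize:
    def test_constant_background_halved(self):
        sino = _disk_sinogram()
        sino.values += 2.0
        sample = sino.values > 2.5
        out = normalize_background(sino, sample_mask=sample)
        exterior = ~sample
        assert np.allclose(out.values[exterior], 1.0, atol=1e-9)

    def test_unit_background_unchanged(self):
        sino = _disk_sinogram()
        sino.values += 1.0
        sample = sino.values > 1.5
        out = normalize_background(sino, sample_mask=sample)
        assert np.allclose(out.values, sino.values)

    def test_row_without_exterior_falls_back_to_global(self):
        sino = _disk_sinogram()
        sino.values += 2.0
        sample = sino.values > 2.5
        sample[4, :] = True  # row 4 has no exterior cells
        out = normalize_background(sino, sample_mask=sample)
        assert 4 in out.meta["normalization"]["fallback_rows"]


class TestBackproject:
    def test_disk_recovered_with_high_dice(self):
        sino = _disk_sinogram(n_x=41, n_omega=18, radius=12.0)
        img, circle = backproject(sino, filtered=True)
        rec = (img > 0.5 * np.nanmax(img)) & circle
        x = sino.x_um
        yy, xx = np.meshgrid(x, x, indexing="ij")
        truth = (yy**2 + xx**2 <= 12.0**2) & circle
        dice = 2 * (rec & truth).sum() / (rec.sum() + truth.sum())
        assert dice > 0.9

    def test_zero_sinogram_gives_zero_map(self):
        sino = _disk_sinogram()
        sino.values[:] = 0.0
        img, circle = backproject(sino, filtered=True)
        assert np.allclose(img[circle], 0.0, atol=1e-12)

    def test_point_phantom_peak_within_one_pixel(self):
        n_x, n_omega = 41, 18
        x = np.arange(n_x) - (n_x - 1) / 2.0
        omega = np.linspace(5, 175, n_omega)
        px, py = 5.0, -3.0  # point position (x, y)
        vals = np.zeros((n_omega, n_x))
        for i, w in enumerate(omega):
            t = np.radians(w)
            proj = px * np.cos(t) + py * np.sin(t)
            vals[i] = np.exp(-0.5 * ((x - proj) / 0.7) ** 2)
        sino = Sinogram(vals, omega, x)
        img, circle = backproject(sino, filtered=True)
        iy, ix = np.unravel_index(np.nanargmax(np.where(circle, img, -np.inf)),
                                  img.shape)
        c = (n_x - 1) / 2.0
        assert abs((ix - c) - px) <= 1.0
        assert abs((c - iy) - py) <= 1.0

    def test_linearity(self):
        s1 = _disk_sinogram(radius=8.0)
        s2 = _disk_sinogram(radius=12.0)
        combo = s1.copy_with(values=2.0 * s1.values + 3.0 * s2.values)
        img_combo, circle = backproject(combo, filtered=True)
        img1, _ = backproject(s1, filtered=True)
        img2, _ = backproject(s2, filtered=True)
        assert np.allclose(img_combo[circle],
                           (2.0 * img1 + 3.0 * img2)[circle], atol=1e-9)

    def test_too_few_angles_rejected(self):
        sino = _disk_sinogram(n_omega=12)
        short = Sinogram(sino.values[:2], sino.omega_deg[:2], sino.x_um)
        with pytest.raises(ValueError):
            backproject(short)

    def test_rotationally_symmetric_phantom_reconstructs_symmetric(self):
        sino = _disk_sinogram(n_x=41, n_omega=18, radius=12.0)
        img, circle = backproject(sino, filtered=True)
        c = (41 - 1) / 2.0
        yy, xx = np.mgrid[:41, :41]
        r = np.hypot(yy - c, xx - c)
        theta = np.arctan2(yy - c, xx - c)
        band = circle & (r > 4) & (r < 9)
        # azimuthal variance well below radial variance
        azi_var = np.var([img[band & (np.abs(((theta - t + np.pi) % (2 * np.pi)) - np.pi) < 0.4)].mean()
                          for t in np.linspace(-np.pi, np.pi, 8, endpoint=False)])
        rad_var = np.var([img[circle & (np.abs(r - rr) < 1.5)].mean()
                          for rr in (2, 6, 10, 13)])
        assert azi_var < 0.05 * rad_var
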