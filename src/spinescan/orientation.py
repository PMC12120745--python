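"""Nanocrystal preferred orientation from the azimuthal intensity of the 002 ring.

The 002 Debye ring is integrated over 36 azimuthal sectors (10° each). Fiber
texture produces two intensity lobes 180° apart (Friedel symmetry); they are
fitted with a double Gaussian whose centers are hard-constrained to χ₀ and
χ₀ + 180°, on top of an isotropic baseline. The degree of preferred
orientation (DoD, 0 = isotropic, 1 = perfectly aligned) is the lobe-area
fraction A_lobes / (A_lobes + A_iso).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .sinogram import Sinogram
from .xrd import DetectorFrame
from . import tomo

N_SECTORS = 36
SECTOR_DEG = 360 // N_SECTORS


@dataclass
class AzimuthalIntensity:
    """Background-corrected 002 intensity in 36 azimuthal sectors."""

    chi_deg: np.ndarray  # sector centers, (−180, 180]
    intensity: np.ndarray
    valid: np.ndarray  # per-sector flag (pixels present)
    id: tuple = (0, 0, 0)

    def __post_init__(self) -> None:
        self.chi_deg = np.asarray(self.chi_deg, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.chi_deg.size != N_SECTORS:
            raise ValueError(f"expected {N_SECTORS} sectors, got {self.chi_deg.size}")


@dataclass
class OrientationFit:
    """Constrained double-Gaussian fit of the azimuthal 002 intensity."""

    peak1_chi_deg: float = np.nan  # raw primary lobe center, (−180, 180]
    axis_deg: float = np.nan  # fiber axis, mapped to (−90, 90]
    separation_deg: float = 180.0
    sigma_deg: float = np.nan
    amplitudes: tuple = (np.nan, np.nan)
    baseline: float = np.nan
    dod: float = np.nan
    rss: float = np.nan
    ok: bool = False

    @property
    def peak2_chi_deg(self) -> float:
        return _wrap180(self.peak1_chi_deg + self.separation_deg)


def _wrap180(a):
    """Wrap an angle to (−180, 180]."""
    w = (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(w == -180.0, 180.0, w) if np.ndim(a) else (
        180.0 if w == -180.0 else float(w)
    )


def integrate_sectors(
    frame: DetectorFrame,
    two_theta_window: tuple[float, float] | None = None,
    background_offset_deg: float = 0.9,
) -> AzimuthalIntensity:
    """Integrate the 002 ring radially in each of the 36 sectors.

    The local background per sector is estimated from two flanking 2θ bands
    (± ``background_offset_deg`` outside the ring window) and subtracted per
    pixel. Sectors without ring pixels are flagged invalid, never raised."""
    beam = frame.beam
    if two_theta_window is None:
        from .xrd import NOMINAL_C_A, two_theta_of_c

        tt0 = two_theta_of_c(NOMINAL_C_A, beam)
        two_theta_window = (tt0 - 0.4, tt0 + 0.4)
    lo, hi = two_theta_window
    width = hi - lo
    tt = beam.two_theta_deg
    chi = beam.chi_deg
    jac = beam.solid_angle_jacobian
    sector = np.clip(((chi + 180.0) // SECTOR_DEG).astype(int), 0, N_SECTORS - 1)
    vals = frame.pixels / jac * np.nanmedian(jac)

    ring = (tt >= lo) & (tt < hi)
    inner = (tt >= lo - background_offset_deg - width / 2) & (tt < lo - background_offset_deg)
    outer = (tt >= hi + background_offset_deg) & (tt < hi + background_offset_deg + width / 2)
    n_ring = np.bincount(sector[ring], minlength=N_SECTORS)
    sum_ring = np.bincount(sector[ring], weights=vals[ring], minlength=N_SECTORS)
    # background: unweighted mean of the two flank levels, so any linear
    # trend in 2θ cancels at the ring position
    means = []
    n_fl = np.zeros(N_SECTORS)
    for band in (inner, outer):
        n_b = np.bincount(sector[band], minlength=N_SECTORS)
        s_b = np.bincount(sector[band], weights=vals[band], minlength=N_SECTORS)
        with np.errstate(invalid="ignore"):
            means.append(np.where(n_b > 0, s_b / np.maximum(n_b, 1), np.nan))
        n_fl += n_b
    with np.errstate(invalid="ignore"):
        bg_per_px = np.nanmean(np.stack(means), axis=0)
    valid = (n_ring > 0) & (n_fl > 0) & np.isfinite(bg_per_px)
    intensity = sum_ring - np.where(np.isfinite(bg_per_px), bg_per_px, 0.0) * n_ring
    intensity[~valid] = np.nan
    centers = -180.0 + SECTOR_DEG * (np.arange(N_SECTORS) + 0.5)
    return AzimuthalIntensity(centers, intensity, valid, frame.id)


def _lobe_model(chi, chi0, sigma, a1, a2, base):
    d1 = _wrap180(chi - chi0)
    d2 = _wrap180(chi - chi0 - 180.0)
    return (
        base
        + a1 * np.exp(-0.5 * (np.asarray(d1) / sigma) ** 2)
        + a2 * np.exp(-0.5 * (np.asarray(d2) / sigma) ** 2)
    )


def fit_orientation(azi: AzimuthalIntensity, min_valid: int = 30,
                    free_separation: bool = False) -> OrientationFit:
    """Fit baseline + two Gaussians with centers locked 180° apart (wrapped
    residuals). ``free_separation=True`` releases the Friedel constraint for
    diagnostics. Non-convergence or too few valid sectors → ok=False."""
    good = azi.valid & np.isfinite(azi.intensity)
    if good.sum() < min_valid:
        return OrientationFit(ok=False)
    chi, y = azi.chi_deg[good], azi.intensity[good]

    base0 = max(float(np.min(y)), 0.0)
    chi0 = float(chi[np.argmax(y)])
    amp0 = max(float(np.max(y) - base0), 1e-12)
    if free_separation:
        def resid(p):
            c1, c2, sigma, a1, a2, base = p
            d1 = _wrap180(chi - c1)
            d2 = _wrap180(chi - c2)
            return (base + a1 * np.exp(-0.5 * (np.asarray(d1) / sigma) ** 2)
                    + a2 * np.exp(-0.5 * (np.asarray(d2) / sigma) ** 2)) - y
        p0 = [chi0, _wrap180(chi0 + 180.0), 20.0, amp0, amp0, base0]
        lb = [-360.0, -360.0, 4.0, 0.0, 0.0, 0.0]
        ub = [360.0, 360.0, 80.0, np.inf, np.inf, np.inf]
    else:
        def resid(p):
            return _lobe_model(chi, *p) - y
        p0 = [chi0, 20.0, amp0, amp0, base0]
        lb = [-360.0, 4.0, 0.0, 0.0, 0.0]
        ub = [360.0, 80.0, np.inf, np.inf, np.inf]
    try:
        res = least_squares(resid, p0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
    except Exception:
        return OrientationFit(ok=False)
    if free_separation:
        c1, c2, sigma, a1, a2, base = res.x
        separation = abs(_wrap180(c2 - c1))
        separation = 360.0 - separation if separation > 180.0 else separation
    else:
        c1, sigma, a1, a2, base = res.x
        separation = 180.0
    # primary lobe = larger amplitude
    if a2 > a1:
        c1, a1, a2 = _wrap180(c1 + 180.0), a2, a1
    c1 = _wrap180(c1)
    axis = c1 if -90.0 < c1 <= 90.0 else _wrap180(c1 - 180.0)
    fit = OrientationFit(
        peak1_chi_deg=float(c1),
        axis_deg=float(axis),
        separation_deg=float(separation),
        sigma_deg=float(sigma),
        amplitudes=(float(a1), float(a2)),
        baseline=float(base),
        rss=float(res.fun @ res.fun),
        ok=bool(res.success),
    )
    fit.dod = degree_of_orientation(fit)
    return fit


def degree_of_orientation(fit: OrientationFit) -> float:
    """DoD = lobe area / (lobe area + isotropic area), clipped to [0, 1].

    Lobe areas use the analytic Gaussian integral; the isotropic area is the
    baseline over the full 360° circle."""
    if not np.isfinite(fit.sigma_deg):
        return np.nan
    a_lobes = sum(fit.amplitudes) * fit.sigma_deg * np.sqrt(2 * np.pi)
    a_iso = max(fit.baseline, 0.0) * 360.0
    if a_lobes + a_iso <= 0:
        return 0.0
    return float(np.clip(a_lobes / (a_lobes + a_iso), 0.0, 1.0))


# ---------------------------------------------------------------------------
# sinograms and ratio maps
# ---------------------------------------------------------------------------


def orientation_sinogram(
    fits: list[list[OrientationFit]],
    omega_deg: np.ndarray,
    x_um: np.ndarray,
) -> tuple[Sinogram, Sinogram]:
    """Assemble (angle, DoD) sinograms from per-(ω, x) orientation fits.

    Points whose fit failed stay masked in both sinograms."""
    n_w, n_x = len(fits), len(fits[0])
    ang = np.full((n_w, n_x), np.nan)
    dod = np.full((n_w, n_x), np.nan)
    for iw in range(n_w):
        for ix in range(n_x):
            f = fits[iw][ix]
            if f is not None and f.ok:
                ang[iw, ix] = f.axis_deg
                dod[iw, ix] = f.dod
    mask = np.isfinite(ang)
    return (
        Sinogram(ang, omega_deg, x_um, mask, quantity="orientation_deg"),
        Sinogram(dod, omega_deg, x_um, mask, quantity="dod"),
    )


def sector_group_sinogram(
    sector_stack: np.ndarray,
    chi_centers_deg: np.ndarray,
    omega_deg: np.ndarray,
    x_um: np.ndarray,
    rel_angles_deg,
    axis_deg: float = 90.0,
) -> Sinogram:
    """Mean sector intensity at the given azimuths relative to the bone main
    axis (each azimuth is paired with its Friedel partner at +180°).

    ``sector_stack`` has shape (n_ω, n_x, 36)."""
    rel = np.atleast_1d(np.asarray(rel_angles_deg, dtype=float))
    targets = np.concatenate([axis_deg + rel, axis_deg + rel + 180.0])
    cols = []
    for t in targets:
        diff = np.abs(_wrap180(chi_centers_deg - t))
        cols.append(int(np.argmin(diff)))
    vals = np.nanmean(sector_stack[:, :, sorted(set(cols))], axis=2)
    return Sinogram(vals, omega_deg, x_um, np.isfinite(vals),
                    quantity=f"sector_{'_'.join(str(int(a)) for a in rel)}")


def ratio_maps(
    sino_axis: Sinogram,
    sino_near: Sinogram,
    sino_far: Sinogram,
    filtered: bool = True,
    eps_frac: float = 1e-3,
):
    """Back-project the axis-parallel 002 intensity and its ratios against
    the <20° and <50° off-axis sector groups.

    Returns ``(map_axis, ratio_near, ratio_far, mask)`` where ratios are
    masked wherever the denominator is below ``eps_frac`` of its maximum."""
    bp_axis, circle = tomo.backproject(sino_axis, filtered=filtered)
    bp_near, _ = tomo.backproject(sino_near, filtered=filtered)
    bp_far, _ = tomo.backproject(sino_far, filtered=filtered)
    out = []
    mask = circle.copy()
    for denom in (bp_near, bp_far):
        lim = eps_frac * np.nanmax(np.abs(denom)) if np.nanmax(np.abs(denom)) > 0 else 1.0
        good = circle & (np.abs(denom) > lim)
        ratio = np.full_like(denom, np.nan)
        ratio[good] = bp_axis[good] / denom[good]
        out.append(ratio)
        mask &= good | ~circle
    return bp_axis, out[0], out[1], mask
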