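"""Forward simulator of the scanning XRD/XRF tomography experiment.

A bone spine cross-section is modelled as a radially symmetric cylinder
(diameter ~35-55 µm) of carbonated apatite whose c-lattice parameter varies
with radius (compressed flanks), wrapped by a thin Zn-enriched rim in the
soft-tissue lining. A pencil beam raster-scans the slice laterally (x) at a
set of rotation angles ω; at every (x, ω) the simulator renders

* one area-detector diffraction frame carrying the apatite 002 Debye ring at
  the Bragg angle of the material-weighted mean lattice spacing along the
  beam chord, with two opposite azimuthal texture lobes (fiber texture along
  the spine axis), isotropic diffuse scatter and counting noise, and
* one XRF energy spectrum with Ca/Zn/Sr Kα lines whose areas follow the
  path-integrated element concentrations (Ca additionally damped by a
  self-absorption term along the exit path toward the fluorescence detector).

Per-angle lateral drift of the rotation stage is injected as a configurable
offset so the analysis-side drift correction can be validated. Ground truth
(phantom parameters, drift, per-point chord-mean lattice spacing) is carried
alongside the data and is never consumed by the analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
from scipy.special import i0e, voigt_profile

from .geometry import BeamGeometry
from .xrd import DetectorFrame, two_theta_of_c

# Kα line energies and K absorption edges, keV (physical constants)
LINE_ENERGY_KEV = {"Ca": 3.691, "Zn": 8.639, "Sr": 14.165}
K_EDGE_KEV = {"Ca": 4.038, "Zn": 9.659, "Sr": 16.105}


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

_PROFILE_SHAPES = ("parabolic", "linear", "piecewise_flat")


@dataclass(frozen=True)
class BonePhantom:
    """Parametric model of one bone cross-section (one slice).

    ``strain_edge`` is the fractional c-lattice deficit of the *local*
    lattice at the outer surface relative to the center: d(R) = c_center *
    (1 + strain_edge). Negative values mean compressed flanks.
    """

    radius_um: float = 22.0
    c_center_A: float = 6.88
    strain_edge: float = -0.001
    strain_profile_shape: str = "parabolic"
    fiber_azimuth_deg: float = 95.0
    dod_true: float = 0.7
    lobe_sigma_deg: float = 18.0
    transition_zone_um: float = 1.0
    # element concentration profiles (arbitrary concentration units, peak 1.0
    # scaled by *_peak); Zn is a Gaussian rim centered at the outer surface
    ca_peak: float = 1.0
    sr_peak: float = 1.0
    zn_peak: float = 1.0
    zn_rim_center_um: float | None = None  # default: at radius_um
    zn_rim_sigma_um: float | None = None  # default: transition_zone_um / 2
    zn_bulk: float = 0.05  # bulk Zn level inside the mineral (absolute)
    ca_absorption_um_inv: float = 0.04  # exit-path self-absorption of Ca Kα

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValueError(f"radius_um must be > 0, got {self.radius_um}")
        if not self.c_center_A > 0:
            raise ValueError(f"c_center_A must be > 0, got {self.c_center_A}")
        if not 0.0 <= self.dod_true <= 1.0:
            raise ValueError(f"dod_true must be in [0, 1], got {self.dod_true}")
        if self.strain_profile_shape not in _PROFILE_SHAPES:
            raise ValueError(
                f"strain_profile_shape must be one of {_PROFILE_SHAPES}, "
                f"got {self.strain_profile_shape!r}"
            )
        if self.transition_zone_um < 0:
            raise ValueError("transition_zone_um must be >= 0")
        if self.lobe_sigma_deg <= 0:
            raise ValueError("lobe_sigma_deg must be > 0")
        if self.zn_center_um < self.radius_um - self.transition_zone_um:
            raise ValueError(
                "zn_rim_center_um must lie at or outside the mineral surface"
            )

    # -- derived geometry --------------------------------------------------

    @property
    def zn_center_um(self) -> float:
        return self.radius_um if self.zn_rim_center_um is None else self.zn_rim_center_um

    @property
    def zn_sigma_um(self) -> float:
        if self.zn_rim_sigma_um is not None:
            return self.zn_rim_sigma_um
        return max(self.transition_zone_um / 2.0, 1e-6)

    @property
    def support_radius_um(self) -> float:
        """Outermost radius with any signal (Zn halo included)."""
        return max(self.radius_um, self.zn_center_um + 2.0 * self.zn_sigma_um)

    # -- radial fields ------------------------------------------------------

    def d_local(self, r_um: np.ndarray) -> np.ndarray:
        """Local c-lattice parameter (Å) at radius r."""
        r = np.asarray(r_um, dtype=float)
        u = np.clip(r / self.radius_um, 0.0, 1.0)
        s = self.strain_edge
        if self.strain_profile_shape == "parabolic":
            f = u**2
        elif self.strain_profile_shape == "linear":
            f = u
        else:  # piecewise_flat: strained shell outside 0.7 R
            f = (u > 0.7).astype(float)
            f[np.isclose(u, 1.0)] = 1.0
        return self.c_center_A * (1.0 + s * f)

    def mineral_density(self, r_um: np.ndarray) -> np.ndarray:
        """Relative mineral density: 1 in the bulk, cosine ramp to 0 across
        the transition zone [R - t, R], 0 outside."""
        r = np.asarray(r_um, dtype=float)
        t = self.transition_zone_um
        if t <= 0:
            return (r <= self.radius_um).astype(float)
        inner = self.radius_um - t
        ramp = 0.5 * (1.0 + np.cos(np.pi * np.clip((r - inner) / t, 0.0, 1.0)))
        return np.where(r <= inner, 1.0, np.where(r <= self.radius_um, ramp, 0.0))

    def concentration(self, element: str, r_um: np.ndarray) -> np.ndarray:
        """Relative concentration of an element at radius r (peak scaled)."""
        r = np.asarray(r_um, dtype=float)
        rho = self.mineral_density(r)
        if element == "Ca":
            return self.ca_peak * rho
        if element == "Sr":
            return self.sr_peak * rho
        if element == "Zn":
            rim = np.exp(-0.5 * ((r - self.zn_center_um) / self.zn_sigma_um) ** 2)
            rim = np.where(r <= self.zn_center_um + 2.0 * self.zn_sigma_um, rim, 0.0)
            return self.zn_peak * rim + self.zn_bulk * rho
        raise ValueError(f"unknown element {element!r}")


def make_phantom(**config) -> BonePhantom:
    """Build a validated :class:`BonePhantom` from keyword parameters."""
    try:
        return BonePhantom(**config)
    except TypeError as exc:
        raise ValueError(str(exc)) from exc


# ---------------------------------------------------------------------------
# scan geometry and noise
# ---------------------------------------------------------------------------


@dataclass
class ScanGeometry:
    """Raster/rotation protocol: lateral positions, rotation angles, beam
    footprint and the per-angle stage drift injected into the simulation
    (in units of x-steps; None = no drift)."""

    x_positions_um: np.ndarray
    omega_deg: np.ndarray
    beam_size_um: float = 4.0
    drift_px: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.x_positions_um = np.asarray(self.x_positions_um, dtype=float)
        self.omega_deg = np.asarray(self.omega_deg, dtype=float)
        if self.omega_deg.ndim != 1 or self.omega_deg.size < 1:
            raise ValueError("omega_deg must be a 1D array of angles")
        if np.any(np.diff(self.omega_deg) <= 0):
            raise ValueError("omega_deg must be strictly increasing")
        if self.omega_deg[0] < 0 or self.omega_deg[-1] > 180:
            raise ValueError("omega_deg must lie within [0, 180] degrees")
        if self.drift_px is not None:
            self.drift_px = np.asarray(self.drift_px, dtype=float)
            if self.drift_px.shape != self.omega_deg.shape:
                raise ValueError("drift_px needs one shift per rotation angle")

    @property
    def step_um(self) -> float:
        return float(np.median(np.diff(self.x_positions_um)))

    @property
    def n_x(self) -> int:
        return self.x_positions_um.size

    @property
    def n_omega(self) -> int:
        return self.omega_deg.size


def default_scan(
    radius_um: float = 22.0,
    step_um: float = 2.0,
    margin_um: float = 8.0,
    n_omega: int = 18,
    beam_size_um: float = 4.0,
    drift_px: np.ndarray | None = None,
    seed: int = 0,
) -> ScanGeometry:
    """Scan covering the phantom diameter plus a margin, with ~10° rotation
    increments over 180° (the tomographic line-scan protocol)."""
    half = radius_um + margin_um
    n_side = int(np.ceil(half / step_um))
    x = np.arange(-n_side, n_side + 1) * step_um
    omega = np.linspace(0.0, 180.0, n_omega, endpoint=False) + 90.0 / n_omega
    return ScanGeometry(x, omega, beam_size_um=beam_size_um, drift_px=drift_px, seed=seed)


def random_drift(n_omega: int, rng: np.random.Generator, bound_steps: float = 2.0) -> np.ndarray:
    """Per-angle lateral stage drift, integer + fractional, bounded by
    ±bound_steps beam steps (mechanical instability of the rotation stage)."""
    return rng.uniform(-bound_steps, bound_steps, size=n_omega)


@dataclass(frozen=True)
class NoiseConfig:
    """Counting statistics / exposure scales.

    ``ring_counts`` is the total 002-ring photon count for a full center
    chord; the default puts the peak-pixel signal-to-noise near 50.
    ``enabled=False`` returns expected (noise-free) intensities.
    """

    enabled: bool = True
    ring_counts: float = 1.2e6
    diffuse_counts: float = 5e4
    detector_bg: float = 1.0  # flat counts per pixel
    ca_counts: float = 6e4  # Kα counts for a full unattenuated center chord
    sr_counts: float = 2.5e3
    zn_counts: float = 2.0e4
    xrf_bg_per_bin: float = 0.5
    xrf_sigma_keV: float = 0.10
    # Voigt widths of the 002 reflection in 2θ (nanocrystalline broadening)
    peak_sigma_deg: float = 0.12
    peak_gamma_deg: float = 0.06


NOISELESS = NoiseConfig(enabled=False)


# ---------------------------------------------------------------------------
# chord sampling
# ---------------------------------------------------------------------------


def _chord_radii(phantom: BonePhantom, b_um: float, ds_um: float):
    """Radii, longitudinal coordinates and path element for a pencil ray at
    impact parameter b; (None, None, ds) when the ray misses the support."""
    r_sup = phantom.support_radius_um
    s_max = r_sup**2 - b_um**2
    if s_max <= 0:
        return None, None, ds_um
    s_max = np.sqrt(s_max)
    n = max(int(np.ceil(2 * s_max / ds_um)), 3)
    s = (np.arange(n) + 0.5) / n * 2 * s_max - s_max
    ds = 2 * s_max / n
    return np.hypot(b_um, s), s, ds


def _beam_offsets(beam_size_um: float, n: int = 5) -> np.ndarray:
    if beam_size_um <= 0:
        return np.array([0.0])
    return (np.arange(n) - (n - 1) / 2) / n * beam_size_um


def chord_mineral(phantom: BonePhantom, b_um: float, beam_size_um: float = 0.0,
                  ds_um: float = 0.25):
    """Material-weighted path length (µm) and mean c-lattice (Å) of the beam
    chord at impact parameter ``b_um``, averaged over the beam footprint.

    Returns ``(length_um, d_mean_A)``; ``d_mean_A`` is NaN when the beam
    misses the mineral.
    """
    lengths, weighted_d = 0.0, 0.0
    for off in _beam_offsets(beam_size_um):
        r, _, ds = _chord_radii(phantom, b_um + off, ds_um)
        if r is None:
            continue
        w = phantom.mineral_density(r) * ds
        lw = w.sum()
        if lw <= 0:
            continue
        lengths += lw
        weighted_d += (w * phantom.d_local(r)).sum()
    n_off = len(_beam_offsets(beam_size_um))
    if lengths <= 1e-9:
        return 0.0, np.nan
    return lengths / n_off, weighted_d / lengths


def chord_element(phantom: BonePhantom, element: str, b_um: float,
                  beam_size_um: float = 0.0, ds_um: float = 0.25,
                  absorption_um_inv: float = 0.0) -> float:
    """Path integral of an element concentration along the beam chord,
    optionally damped by exit-path self-absorption through the mineral
    toward the fluorescence detector (+x side of the lab frame)."""
    total = 0.0
    r_eff = phantom.radius_um - phantom.transition_zone_um / 2.0
    for off in _beam_offsets(beam_size_um):
        b = b_um + off
        r, s, ds = _chord_radii(phantom, b, ds_um)
        if r is None:
            continue
        conc = phantom.concentration(element, r)
        if absorption_um_inv > 0:
            inside = np.sqrt(np.maximum(r_eff**2 - s**2, 0.0))
            exit_len = np.maximum(inside - b, 0.0)
            conc = conc * np.exp(-absorption_um_inv * exit_len)
        total += (conc * ds).sum()
    return total / len(_beam_offsets(beam_size_um))


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _render_cache(beam: BeamGeometry, two_theta_nominal: float):
    """Annulus pixel selection around the nominal ring plus the diffuse
    background template (normalized to unit total counts)."""
    tt = beam.two_theta_deg
    chi = np.radians(beam.chi_deg)
    jac = beam.solid_angle_jacobian
    ring_sel = np.abs(tt - two_theta_nominal) < 1.5
    # low-angle diffuse scatter: densities per radian, ~2θ·exp(−2θ/τ)
    tau = np.radians(3.0)
    tt_rad = np.radians(tt)
    diffuse = tt_rad * np.exp(-tt_rad / tau) / (2 * np.pi) * jac
    diffuse = diffuse / diffuse.sum()
    return (
        ring_sel,
        np.radians(tt[ring_sel]),
        chi[ring_sel],
        jac[ring_sel],
        diffuse,
    )


def _azimuthal_density(chi_rad: np.ndarray, chi0_deg: float, dod: float,
                       lobe_sigma_deg: float) -> np.ndarray:
    """Azimuthal intensity density (per radian, integrates to 1 over 2π):
    isotropic floor plus two opposite von-Mises lobes; ``dod`` is the lobe
    area fraction."""
    kappa = 1.0 / np.radians(lobe_sigma_deg) ** 2
    chi0 = np.radians(chi0_deg)
    lobes = np.exp(kappa * (np.cos(chi_rad - chi0) - 1.0)) + np.exp(
        kappa * (np.cos(chi_rad - chi0 - np.pi) - 1.0)
    )
    lobes = lobes / (4 * np.pi * i0e(kappa))
    return (1.0 - dod) / (2 * np.pi) + dod * lobes


def simulate_frame(
    phantom: BonePhantom,
    x_um: float,
    omega_deg: float,
    beam: BeamGeometry,
    scan: ScanGeometry | None = None,
    noise: NoiseConfig = NoiseConfig(),
    rng: np.random.Generator | None = None,
    drift_um: float = 0.0,
    frame_id: tuple = (0, 0, 0),
) -> DetectorFrame:
    """Render one diffraction frame for the beam at lateral position x.

    The 002 ring radius encodes the material-weighted mean c-lattice along
    the (drift-offset) beam chord; azimuthal intensity carries the fiber
    texture; diffuse scatter and a flat detector floor complete the image.
    """
    beam_size = scan.beam_size_um if scan is not None else 0.0
    length, d_mean = chord_mineral(phantom, x_um - drift_um, beam_size)
    nominal_tt = two_theta_of_c(phantom.c_center_A, beam)
    ring_sel, tt_rad, chi_rad, jac, diffuse_tpl = _render_cache(beam, round(nominal_tt, 3))

    expected = np.full(beam.detector_shape_px, float(noise.detector_bg))
    rel = length / (2 * phantom.radius_um)
    if length > 0 and np.isfinite(d_mean):
        tt_ring = np.radians(two_theta_of_c(d_mean, beam))
        radial = voigt_profile(
            tt_rad - tt_ring,
            np.radians(noise.peak_sigma_deg),
            np.radians(noise.peak_gamma_deg),
        )
        azi = _azimuthal_density(
            chi_rad, phantom.fiber_azimuth_deg, phantom.dod_true, phantom.lobe_sigma_deg
        )
        expected[ring_sel] += noise.ring_counts * rel * radial * azi * jac
        expected += noise.diffuse_counts * rel * diffuse_tpl

    if noise.enabled:
        if rng is None:
            rng = np.random.default_rng()
        pixels = rng.poisson(expected).astype(np.float64)
    else:
        pixels = expected
    return DetectorFrame(pixels=pixels, beam=beam, id=frame_id,
                         x_um=x_um, omega_deg=omega_deg)


# ---------------------------------------------------------------------------
# XRF spectra
# ---------------------------------------------------------------------------


@dataclass
class XRFSpectrum:
    """One fluorescence spectrum: energy bin centers (keV) and counts."""

    energy_bins_keV: np.ndarray
    counts: np.ndarray
    livetime_s: float = 0.5

    def __post_init__(self) -> None:
        self.energy_bins_keV = np.asarray(self.energy_bins_keV, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.energy_bins_keV.shape != self.counts.shape:
            raise ValueError("energy bins and counts must have the same shape")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_width_keV(self) -> float:
        return float(np.median(np.diff(self.energy_bins_keV)))


def default_energy_bins(max_keV: float = 20.0, step_keV: float = 0.02) -> np.ndarray:
    return np.arange(step_keV / 2, max_keV, step_keV)


def simulate_xrf_spectrum(
    phantom: BonePhantom,
    x_um: float,
    omega_deg: float,
    beam: BeamGeometry,
    scan: ScanGeometry | None = None,
    noise: NoiseConfig = NoiseConfig(),
    rng: np.random.Generator | None = None,
    drift_um: float = 0.0,
    energy_bins_keV: np.ndarray | None = None,
) -> XRFSpectrum:
    """Render one XRF spectrum: Gaussian Kα peaks for every element whose K
    edge lies below the beam energy, areas proportional to the chord-integrated
    concentration (Ca attenuated by self-absorption on the exit path)."""
    if energy_bins_keV is None:
        energy_bins_keV = default_energy_bins()
    bins = np.asarray(energy_bins_keV, dtype=float)
    dE = float(np.median(np.diff(bins)))
    beam_size = scan.beam_size_um if scan is not None else 0.0
    b = x_um - drift_um
    norm = 2 * phantom.radius_um

    expected = np.full(bins.shape, float(noise.xrf_bg_per_bin))
    scale = {"Ca": noise.ca_counts, "Sr": noise.sr_counts, "Zn": noise.zn_counts}
    for el, line in LINE_ENERGY_KEV.items():
        if beam.energy_keV <= K_EDGE_KEV[el]:
            continue  # line cannot be excited (e.g. Sr at 13 keV)
        absorption = phantom.ca_absorption_um_inv if el == "Ca" else 0.0
        area = scale[el] * chord_element(
            phantom, el, b, beam_size, absorption_um_inv=absorption
        ) / norm
        if area <= 0:
            continue
        sig = noise.xrf_sigma_keV
        expected += area * dE * np.exp(-0.5 * ((bins - line) / sig) ** 2) / (
            sig * np.sqrt(2 * np.pi)
        )

    if noise.enabled:
        if rng is None:
            rng = np.random.default_rng()
        counts = rng.poisson(expected).astype(np.float64)
    else:
        counts = expected
    return XRFSpectrum(energy_bins_keV=bins, counts=counts)


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------


@dataclass
class ScanDataset:
    """All frames and spectra of one tomographic slice scan, plus ground
    truth (used only by tests, never by the analysis path)."""

    frames: np.ndarray  # (n_omega, n_x, rows, cols) expected or Poisson counts
    spectra: np.ndarray  # (n_omega, n_x, n_bins)
    energy_bins_keV: np.ndarray
    beam: BeamGeometry
    scan: ScanGeometry
    truth: dict = field(default_factory=dict)
    slice_index: int = 0

    @property
    def n_omega(self) -> int:
        return self.frames.shape[0]

    @property
    def n_x(self) -> int:
        return self.frames.shape[1]

    def frame(self, i_omega: int, i_x: int) -> DetectorFrame:
        return DetectorFrame(
            pixels=np.asarray(self.frames[i_omega, i_x], dtype=float),
            beam=self.beam,
            id=(self.slice_index, i_x, i_omega),
            x_um=float(self.scan.x_positions_um[i_x]),
            omega_deg=float(self.scan.omega_deg[i_omega]),
        )

    def spectrum(self, i_omega: int, i_x: int) -> XRFSpectrum:
        return XRFSpectrum(
            energy_bins_keV=self.energy_bins_keV,
            counts=np.asarray(self.spectra[i_omega, i_x], dtype=float),
        )


def simulate_scan(
    phantom: BonePhantom,
    beam: BeamGeometry,
    scan: ScanGeometry,
    noise: NoiseConfig = NoiseConfig(),
    seed: int | None = None,
    slice_index: int = 0,
) -> ScanDataset:
    """Simulate all (x, ω) points of one slice. Deterministic given the seed
    (``scan.seed`` unless overridden)."""
    x = scan.x_positions_um
    if x.min() > -phantom.radius_um or x.max() < phantom.radius_um:
        raise ValueError("x_positions_um must cover the phantom diameter")
    rng = np.random.default_rng(scan.seed if seed is None else seed)
    drift = np.zeros(scan.n_omega) if scan.drift_px is None else scan.drift_px
    bins = default_energy_bins()

    frames = np.empty((scan.n_omega, scan.n_x) + beam.detector_shape_px, dtype=np.float32)
    spectra = np.empty((scan.n_omega, scan.n_x, bins.size), dtype=np.float32)
    d_path = np.full((scan.n_omega, scan.n_x), np.nan)
    chord = np.zeros((scan.n_omega, scan.n_x))

    for iw, w in enumerate(scan.omega_deg):
        drift_um = drift[iw] * scan.step_um
        for ix, xi in enumerate(x):
            fr = simulate_frame(
                phantom, xi, w, beam, scan, noise, rng, drift_um,
                frame_id=(slice_index, ix, iw),
            )
            frames[iw, ix] = fr.pixels
            sp = simulate_xrf_spectrum(
                phantom, xi, w, beam, scan, noise, rng, drift_um, bins
            )
            spectra[iw, ix] = sp.counts
            length, dm = chord_mineral(phantom, xi - drift_um, scan.beam_size_um)
            chord[iw, ix] = length
            d_path[iw, ix] = dm

    truth = {
        "phantom": asdict(phantom),
        "drift_px": drift.tolist(),
        "d_path_mean_A": d_path,
        "chord_um": chord,
    }
    return ScanDataset(
        frames=frames,
        spectra=spectra,
        energy_bins_keV=bins,
        beam=beam,
        scan=scan,
        truth=truth,
        slice_index=slice_index,
    )
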