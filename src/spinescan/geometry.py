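"""Beam/detector geometry and the angular coordinates of detector pixels.

A single flat area detector sits orthogonal to the incident beam at distance
``distance_mm``. Every pixel is mapped once to its scattering angle 2θ and its
azimuth χ around the direct beam; those maps are cached per geometry because
every frame of a scan shares them.

Azimuth convention: χ = 0 along the detector +horizontal axis (increasing
column), counterclockwise positive when looking downstream (row index
increasing downward on the image), range (−180°, 180°].
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

#: hc in keV·Å, used to convert photon energy to wavelength.
HC_KEV_A = 12.398419


def wavelength_from_energy(energy_keV: float) -> float:
    """Photon wavelength λ in Å for a given energy in keV (λ = hc/E)."""
    if not energy_keV > 0:
        raise ValueError(f"energy_keV must be positive, got {energy_keV}")
    return HC_KEV_A / energy_keV


@dataclass(frozen=True)
class BeamGeometry:
    """Acquisition geometry of the diffraction detector.

    Defaults emulate an 18 keV microbeam setup with a hybrid pixel detector
    (172 µm pitch) placed so the apatite 002 ring (2θ ≈ 11.5°) sits mid-way
    between beam center and detector edge.
    """

    energy_keV: float = 18.0
    distance_mm: float = 70.0
    pixel_size_um: float = 172.0
    beam_center_px: tuple[float, float] = (127.5, 127.5)  # (row, col)
    detector_shape_px: tuple[int, int] = (256, 256)  # (rows, cols)
    diffraction_order_n: int = 1

    def __post_init__(self) -> None:
        if not self.energy_keV > 0:
            raise ValueError("energy_keV must be positive")
        if not self.distance_mm > 0:
            raise ValueError("distance_mm must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.diffraction_order_n < 1:
            raise ValueError("diffraction_order_n must be >= 1")
        nr, nc = self.detector_shape_px
        r0, c0 = self.beam_center_px
        # allow the direct beam slightly off the panel, but not far away
        if not (-nr <= r0 <= 2 * nr and -nc <= c0 <= 2 * nc):
            raise ValueError("beam_center_px far outside detector bounds")

    @property
    def wavelength_A(self) -> float:
        return wavelength_from_energy(self.energy_keV)

    # -- cached per-pixel angular maps ------------------------------------

    @property
    def two_theta_deg(self) -> np.ndarray:
        """2D map of scattering angle 2θ (degrees) per pixel."""
        return _pixel_maps(self)[0]

    @property
    def chi_deg(self) -> np.ndarray:
        """2D map of azimuth χ (degrees, (−180, 180]) per pixel."""
        return _pixel_maps(self)[1]

    @property
    def solid_angle_jacobian(self) -> np.ndarray:
        """Pixel area expressed in (Δ2θ × Δχ) radians² — the weight that turns
        an intensity density per unit (2θ, χ) into counts in one pixel."""
        return _pixel_maps(self)[2]

    def two_theta_of_radius_mm(self, r_mm: np.ndarray | float) -> np.ndarray | float:
        return np.degrees(np.arctan2(r_mm, self.distance_mm))

    def radius_mm_of_two_theta(self, two_theta_deg: np.ndarray | float):
        return self.distance_mm * np.tan(np.radians(two_theta_deg))


@lru_cache(maxsize=8)
def _pixel_maps(beam: BeamGeometry):
    nr, nc = beam.detector_shape_px
    r0, c0 = beam.beam_center_px
    p_mm = beam.pixel_size_um * 1e-3
    rows = np.arange(nr)[:, None]
    cols = np.arange(nc)[None, :]
    dx = (cols - c0) * p_mm  # +horizontal
    dy = (r0 - rows) * p_mm  # +vertical (row index grows downward)
    r = np.hypot(dx, dy)
    two_theta = np.degrees(np.arctan2(r, beam.distance_mm))
    chi = np.degrees(np.arctan2(dy, dx))
    # map -180 -> +180 so the range is (-180, 180]
    chi = np.where(chi <= -180.0, 180.0, chi)
    # d(2θ)/dr = cos²(2θ)/L ; dχ/d(arc) = 1/r
    cos2t = np.cos(np.radians(two_theta))
    with np.errstate(divide="ignore"):
        jac = (p_mm * cos2t**2 / beam.distance_mm) * (p_mm / np.where(r > 0, r, np.inf))
    return two_theta, chi, jac
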