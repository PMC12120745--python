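"""Sinogram container shared by the XRF, orientation, tomo and strain stages.

A sinogram here is one scalar quantity sampled over (rotation angle ω,
lateral position x) for a single slice: rows are line scans at one ω. The
validity mask marks cells that carry a usable measurement (True = valid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Sinogram:
    values: np.ndarray  # shape (n_omega, n_x)
    omega_deg: np.ndarray  # shape (n_omega,)
    x_um: np.ndarray  # shape (n_x,)
    mask: np.ndarray | None = None  # True where valid
    quantity: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.omega_deg = np.asarray(self.omega_deg, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be 2D (n_omega, n_x)")
        if self.values.shape != (self.omega_deg.size, self.x_um.size):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"({self.omega_deg.size} angles, {self.x_um.size} positions)"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")

    @property
    def n_omega(self) -> int:
        return self.values.shape[0]

    @property
    def n_x(self) -> int:
        return self.values.shape[1]

    @property
    def step_um(self) -> float:
        return float(np.median(np.diff(self.x_um)))

    def copy_with(self, values=None, mask=None, **meta) -> "Sinogram":
        new = Sinogram(
            values=self.values.copy() if values is None else np.asarray(values, float),
            omega_deg=self.omega_deg.copy(),
            x_um=self.x_um.copy(),
            mask=self.mask.copy() if mask is None else np.asarray(mask, bool),
            quantity=self.quantity,
            meta=dict(self.meta),
        )
        new.meta.update(meta)
        return new

    def masked(self) -> np.ndarray:
        """Values with invalid cells as NaN."""
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out


class ElementSinogram(Sinogram):
    """Sinogram of background-subtracted fluorescence counts for one element."""

    @property
    def element(self) -> str:
        return self.quantity
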