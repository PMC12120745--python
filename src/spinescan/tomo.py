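"""Sinogram drift correction, background normalization and back-projection.

Mechanical play in the rotation stage shifts each line scan laterally by an
unknown per-angle offset. Strontium is dilute, homogeneous in the mineral and
barely self-absorbed, so every row of the Sr sinogram is (up to noise) the
same projected profile: rows are co-aligned by cross-correlation against an
iteratively refined mean-row template, with sub-pixel refinement from a
parabolic interpolation of the correlation peak. The same shifts are then
applied to every co-acquired sinogram (Ca, Zn, d-spacing, orientation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon

from .sinogram import Sinogram


@dataclass
class DriftModel:
    """Per-angle lateral offsets (in x-step units) and the rotation-axis
    anchor used to resolve the global alignment constant."""

    shifts_px: np.ndarray
    reference_center: float
    method: str = "xcorr-meanrow"
    interpolated: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        self.shifts_px = np.asarray(self.shifts_px, dtype=float)
        if self.interpolated.size == 0:
            self.interpolated = np.zeros(self.shifts_px.size, dtype=bool)


def _xcorr_shift(row: np.ndarray, template: np.ndarray, max_shift: int,
                 subpixel: bool) -> float:
    """Lag of ``row`` relative to ``template`` maximizing cross-correlation,
    searched over ±max_shift, with optional parabolic sub-pixel refinement."""
    lags = np.arange(-max_shift, max_shift + 1)
    c = np.empty(lags.size)
    n = row.size
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = row[k:], template[: n - k]
        else:
            a, b = row[: n + k], template[-k:]
        c[i] = float(a @ b)
    i_best = int(np.argmax(c))
    shift = float(lags[i_best])
    if subpixel and 0 < i_best < lags.size - 1:
        cm, c0, cp = c[i_best - 1], c[i_best], c[i_best + 1]
        denom = cm - 2 * c0 + cp
        if denom < 0:
            shift += 0.5 * (cm - cp) / denom
    return shift


def estimate_drift(
    sr: Sinogram,
    max_shift: int = 5,
    subpixel: bool = True,
    n_iter: int = 2,
    min_signal_snr: float = 5.0,
) -> DriftModel:
    """Per-angle lateral shift of each Sr sinogram row.

    Rows are aligned to a mean-row template (refined over ``n_iter`` passes);
    the global constant is anchored so the aligned template's center of mass
    sits on the grid center (one shared rotation center). Rows without
    usable signal get a shift interpolated from neighboring angles and are
    flagged."""
    vals = np.where(sr.mask, sr.values, 0.0)
    n_w, n_x = vals.shape
    # signal presence per row: peak above noise floor of the row's low cells
    weak = np.zeros(n_w, dtype=bool)
    for i in range(n_w):
        row = vals[i]
        low = row[row <= np.quantile(row, 0.25)]
        floor = np.median(low)
        mad = 1.4826 * np.median(np.abs(low - floor)) + 1e-12
        weak[i] = (row.max() - floor) / mad < min_signal_snr

    usable = ~weak
    if usable.sum() < 2:
        raise ValueError("Sr sinogram has too few rows with signal to align")

    shifts = np.zeros(n_w)
    template = vals[usable].mean(axis=0)
    idx = np.arange(n_x, dtype=float)
    for _ in range(n_iter):
        for i in np.flatnonzero(usable):
            shifts[i] = _xcorr_shift(vals[i], template, max_shift, subpixel)
        aligned = [np.interp(idx + shifts[i], idx, vals[i]) for i in np.flatnonzero(usable)]
        template = np.mean(aligned, axis=0)
    # anchor: rotation center at the grid center
    com = float((template * idx).sum() / max(template.sum(), 1e-12))
    center = (n_x - 1) / 2.0
    shifts[usable] += com - center
    if weak.any():
        shifts[weak] = np.interp(
            np.flatnonzero(weak), np.flatnonzero(usable), shifts[usable]
        )
    return DriftModel(shifts_px=shifts, reference_center=center,
                      method=f"xcorr-meanrow(subpixel={subpixel})",
                      interpolated=weak)


def apply_shifts(sino: Sinogram, drift: DriftModel, mode: str = "linear") -> Sinogram:
    """Undo the per-angle drift on any co-acquired sinogram.

    ``linear`` resamples each row at x + shift with linear interpolation
    (masked cells poison their neighbors); ``integer`` rolls by the rounded
    shift and is exact for integer drifts."""
    if drift.shifts_px.size != sino.n_omega:
        raise ValueError("drift model does not match sinogram angle count")
    vals = sino.masked()
    out = np.full_like(vals, np.nan)
    idx = np.arange(sino.n_x, dtype=float)
    for i, s in enumerate(drift.shifts_px):
        if mode == "integer":
            k = int(round(s))
            if k == 0:
                out[i] = vals[i]
            elif k > 0:
                out[i, : sino.n_x - k] = vals[i, k:]
            else:
                out[i, -k:] = vals[i, : sino.n_x + k]
        elif mode == "linear":
            out[i] = np.interp(idx + s, idx, vals[i], left=np.nan, right=np.nan)
            # nan-poisoning: any cell interpolated from an invalid neighbor
            bad = np.interp(idx + s, idx, (~sino.mask[i]).astype(float),
                            left=1.0, right=1.0) > 1e-9
            out[i, bad] = np.nan
        else:
            raise ValueError(f"unknown interpolation mode {mode!r}")
    mask = np.isfinite(out)
    return sino.copy_with(values=np.where(mask, out, np.nan), mask=mask,
                          drift_applied=drift.shifts_px.tolist(),
                          drift_interp=mode)


def normalize_background(
    sino: Sinogram,
    sample_mask: np.ndarray | None = None,
    mode: str = "per_row",
) -> Sinogram:
    """Divide each row by its off-sample background level (median of the
    exterior cells); rows without exterior cells fall back to the global
    background and are flagged in the metadata."""
    if mode not in ("per_row", "global"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if sample_mask is None:
        sample_mask = detect_sample_extent(sino)
    exterior = sino.mask & ~sample_mask
    if not exterior.any():
        raise ValueError("no exterior cells available for background estimate")
    global_bg = float(np.median(sino.values[exterior]))
    if global_bg == 0:
        global_bg = 1.0
    vals = sino.values.copy()
    flagged = []
    for i in range(sino.n_omega):
        ext = exterior[i]
        if mode == "global" or ext.sum() < 2:
            bg = global_bg
            if mode == "per_row":
                flagged.append(i)
        else:
            bg = float(np.median(sino.values[i, ext]))
            if bg == 0:
                bg = global_bg
        vals[i] = sino.values[i] / bg
    return sino.copy_with(values=vals, normalization={
        "mode": mode, "global_bg": global_bg, "fallback_rows": flagged})


def detect_sample_extent(sino: Sinogram, k: float = 5.0) -> np.ndarray:
    """Heuristic sample support: cells well above the sinogram's low-level
    background (median + k·MAD of the lower half of valid values)."""
    vals = sino.values[sino.mask]
    lo = np.quantile(vals, 0.5)
    low_half = vals[vals <= lo]
    mad = 1.4826 * np.median(np.abs(low_half - np.median(low_half))) + 1e-12
    thresh = np.median(low_half) + k * mad
    return sino.mask & (sino.values > thresh)


def backproject(
    sino: Sinogram,
    filtered: bool = True,
    output_size: int | None = None,
    fill_value: float = 0.0,
):
    """Parallel-beam back-projection of one sinogram (ramp-filtered by
    default, plain smearing with ``filtered=False``).

    Returns ``(image, inscribed_circle_mask)``; pixels outside the inscribed
    circle are NaN. Requires at least 3 angles."""
    if sino.n_omega < 3:
        raise ValueError("back-projection needs at least 3 rotation angles")
    vals = np.where(sino.mask, sino.values, fill_value)
    size = output_size or sino.n_x
    img = iradon(
        vals.T,
        theta=sino.omega_deg,
        output_size=size,
        filter_name="ramp" if filtered else None,
        circle=True,
    )
    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2.0
    circle = (yy - c) ** 2 + (xx - c) ** 2 <= (size / 2.0) ** 2
    img = np.where(circle, img, np.nan)
    return img, circle
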