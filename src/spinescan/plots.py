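"""Figure exports: sinogram heatmaps, normalized trend scatter, strain
boxplots and orientation arrow maps. All functions save to a path and
return it; they are thin matplotlib wrappers used by the pipeline."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .sinogram import Sinogram


def plot_sinogram(sino: Sinogram, path: str | Path, cmap: str = "viridis") -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        sino.masked(), aspect="auto", cmap=cmap, origin="lower",
        extent=[sino.x_um[0], sino.x_um[-1], sino.omega_deg[0], sino.omega_deg[-1]],
    )
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("ω (deg)")
    ax.set_title(sino.quantity)
    fig.colorbar(im, ax=ax)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_normalized_trends(profiles, fits, path: str | Path) -> Path:
    """Scatter of d versus normalized width with per-angle trend curves."""
    fig, ax = plt.subplots(figsize=(5, 4))
    grid = np.linspace(0, 100, 101)
    for p, f in zip(profiles, fits):
        ax.plot(p.position_pct, p.d_values, ".", ms=3, alpha=0.4)
        if f.ok:
            ax.plot(grid, np.polyval(f.coeffs, grid), "-", lw=0.8, alpha=0.6)
    ax.set_xlabel("normalized width (%)")
    ax.set_ylabel("d-spacing (Å)")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_strain_boxplot(groups: dict[str, list[float]], path: str | Path) -> Path:
    """Per-species boxplot of sample apparent strains (percent)."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(list(groups.values()), tick_labels=list(groups.keys()))
    ax.set_ylabel("apparent strain (%)")
    ax.axhline(0.0, color="gray", lw=0.5)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_orientation_arrows(angle_sino: Sinogram, dod_sino: Sinogram,
                            path: str | Path) -> Path:
    """Orientation sinogram with arrows: direction = fiber axis, length = DoD."""
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(
        angle_sino.masked(), aspect="auto", cmap="twilight", origin="lower",
        vmin=-90, vmax=90,
    )
    fig.colorbar(im, ax=ax, label="orientation (deg)")
    for iw in range(angle_sino.n_omega):
        for ix in range(angle_sino.n_x):
            if not (angle_sino.mask[iw, ix] and dod_sino.mask[iw, ix]):
                continue
            a = np.radians(angle_sino.values[iw, ix])
            L = 0.45 * dod_sino.values[iw, ix]
            ax.plot(
                [ix - L * np.cos(a), ix + L * np.cos(a)],
                [iw - L * np.sin(a), iw + L * np.sin(a)],
                "r-", lw=0.7,
            )
    ax.set_xlabel("x index")
    ax.set_ylabel("ω index")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
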