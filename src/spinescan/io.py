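"""On-disk layout of simulated scans and analysis products.

A scan directory holds: ``frames.tif`` (multi-page TIFF, one page per
(ω, x) point in row-major order), ``spectra.csv`` (one row per point, one
column per energy bin), ``geometry.json`` (beam + scan metadata) and
``truth.json`` (simulation ground truth — written for reference, never read
by the analysis path). Sinograms travel as CSV + TIFF pairs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import BeamGeometry
from .sinogram import Sinogram
from .synthetic import BonePhantom, ScanDataset, ScanGeometry


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return super().default(o)


def save_dataset(dataset: ScanDataset, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    n_w, n_x = dataset.n_omega, dataset.n_x
    tifffile.imwrite(
        d / "frames.tif",
        dataset.frames.reshape((n_w * n_x,) + dataset.frames.shape[2:]),
    )
    spec = pd.DataFrame(
        dataset.spectra.reshape(n_w * n_x, -1),
        columns=[f"{e:.3f}" for e in dataset.energy_bins_keV],
    )
    spec.insert(0, "i_omega", np.repeat(np.arange(n_w), n_x))
    spec.insert(1, "i_x", np.tile(np.arange(n_x), n_w))
    spec.to_csv(d / "spectra.csv", index=False)
    geom = {
        "beam": asdict(dataset.beam),
        "scan": {
            "x_positions_um": dataset.scan.x_positions_um,
            "omega_deg": dataset.scan.omega_deg,
            "beam_size_um": dataset.scan.beam_size_um,
            "seed": dataset.scan.seed,
        },
        "slice_index": dataset.slice_index,
    }
    (d / "geometry.json").write_text(json.dumps(geom, cls=_NumpyEncoder, indent=1))
    (d / "truth.json").write_text(json.dumps(dataset.truth, cls=_NumpyEncoder))
    return d


def load_dataset(directory: str | Path) -> ScanDataset:
    d = Path(directory)
    geom = json.loads((d / "geometry.json").read_text())
    beam_kw = geom["beam"]
    beam_kw["beam_center_px"] = tuple(beam_kw["beam_center_px"])
    beam_kw["detector_shape_px"] = tuple(beam_kw["detector_shape_px"])
    beam = BeamGeometry(**beam_kw)
    scan = ScanGeometry(
        x_positions_um=np.asarray(geom["scan"]["x_positions_um"]),
        omega_deg=np.asarray(geom["scan"]["omega_deg"]),
        beam_size_um=geom["scan"]["beam_size_um"],
        seed=geom["scan"]["seed"],
    )
    frames = tifffile.imread(d / "frames.tif")
    n_w, n_x = scan.n_omega, scan.n_x
    frames = np.asarray(frames).reshape((n_w, n_x) + frames.shape[1:])
    spec = pd.read_csv(d / "spectra.csv")
    energy = np.array([float(c) for c in spec.columns[2:]])
    spectra = spec.iloc[:, 2:].to_numpy().reshape(n_w, n_x, -1)
    truth = {}
    truth_file = d / "truth.json"
    if truth_file.exists():
        truth = json.loads(truth_file.read_text())
    return ScanDataset(
        frames=frames, spectra=spectra, energy_bins_keV=energy,
        beam=beam, scan=scan, truth=truth,
        slice_index=geom.get("slice_index", 0),
    )


def save_sinogram(sino: Sinogram, path_base: str | Path) -> None:
    """Write one sinogram as CSV (values, with x/ω headers) + float TIFF."""
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(sino.masked(), columns=[f"{x:.3f}" for x in sino.x_um])
    df.insert(0, "omega_deg", sino.omega_deg)
    df.to_csv(base.with_suffix(".csv"), index=False)
    tifffile.imwrite(base.with_suffix(".tif"), sino.values.astype(np.float32))


def load_sinogram(csv_path: str | Path, quantity: str = "") -> Sinogram:
    df = pd.read_csv(csv_path)
    omega = df["omega_deg"].to_numpy()
    x = np.array([float(c) for c in df.columns[1:]])
    vals = df.iloc[:, 1:].to_numpy()
    return Sinogram(vals, omega, x, np.isfinite(vals), quantity=quantity)


def save_json(obj: dict, path: str | Path) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(obj, cls=_NumpyEncoder, indent=1))


def phantom_from_dict(cfg: dict) -> BonePhantom:
    return BonePhantom(**cfg)
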