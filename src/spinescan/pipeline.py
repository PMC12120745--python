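"""Staged pipeline: simulate → reduce → tomo → strain.

Every stage reads the stage before it through the files it wrote, records a
manifest (config hash, inputs, outputs) and is idempotent: re-running a
stage with the same config and seed reproduces its outputs. A two-species
synthetic study is described by one :class:`RunConfig`; per-sample phantom
parameters (radius, strain level) are drawn deterministically from the run
seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import io, orientation, plots, strain, tomo, xrf
from .geometry import BeamGeometry
from .synthetic import (
    BonePhantom,
    NoiseConfig,
    ScanGeometry,
    default_scan,
    random_drift,
    simulate_scan,
)
from .xrd import reduce_scan

STAGES = ("simulate", "reduce", "tomo", "strain")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Fully serializable description of one synthetic study run."""

    seed: int = 0
    outdir: str = "run"
    species: dict = field(default_factory=lambda: {
        "medaka": {"strain_edge": -0.001, "n_samples": 3},
        "zebrafish": {"strain_edge": -0.0007, "n_samples": 3},
    })
    sample_variation: dict = field(default_factory=lambda: {
        "strain_sd": 0.0002,
        "radius_range_um": [17.5, 27.5],
    })
    beam: dict = field(default_factory=dict)
    scan: dict = field(default_factory=lambda: {
        "step_um": 2.0, "n_omega": 18, "margin_um": 8.0,
        "beam_size_um": 4.0, "drift_bound_steps": 2.0,
    })
    noise: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=lambda: {
        "trend_model": "quadratic", "robust": False,
        "deprojection": True, "filtered_bp": True,
        "paired": False, "orientation": True,
    })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in data.items():
            if not hasattr(cfg, key):
                raise PipelineError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                merged = dict(getattr(cfg, key))
                merged.update(val)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, val)
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "outdir": self.outdir, "species": self.species,
            "sample_variation": self.sample_variation, "beam": self.beam,
            "scan": self.scan, "noise": self.noise, "analysis": self.analysis,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    # -- derived objects ----------------------------------------------------

    def beam_geometry(self) -> BeamGeometry:
        kw = dict(self.beam)
        if "beam_center_px" in kw:
            kw["beam_center_px"] = tuple(kw["beam_center_px"])
        if "detector_shape_px" in kw:
            kw["detector_shape_px"] = tuple(kw["detector_shape_px"])
        return BeamGeometry(**kw)

    def noise_config(self) -> NoiseConfig:
        return NoiseConfig(**self.noise)

    def samples(self):
        """Deterministic per-sample phantom parameters for the whole study."""
        out = []
        r_lo, r_hi = self.sample_variation.get("radius_range_um", [17.5, 27.5])
        s_sd = self.sample_variation.get("strain_sd", 0.0002)
        for i_sp, (name, spec) in enumerate(sorted(self.species.items())):
            for j in range(int(spec.get("n_samples", 3))):
                rng = np.random.default_rng([self.seed, i_sp, j])
                phantom_kw = {
                    k: v for k, v in spec.items()
                    if k not in ("n_samples", "strain_edge")
                }
                phantom_kw.setdefault("radius_um", float(rng.uniform(r_lo, r_hi)))
                phantom_kw["strain_edge"] = float(
                    spec.get("strain_edge", -0.001) + rng.normal(0.0, s_sd)
                )
                out.append({
                    "species": name,
                    "sample": f"{name}_{j}",
                    "phantom": phantom_kw,
                    "scan_seed": int(rng.integers(0, 2**31 - 1)),
                })
        return out


def _manifest_path(outdir: Path, stage: str) -> Path:
    return outdir / f"manifest_{stage}.json"


def _write_manifest(outdir: Path, stage: str, cfg: RunConfig,
                    inputs: list[str], outputs: list[str]) -> None:
    io.save_json({
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": sorted(inputs),
        "outputs": sorted(outputs),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }, _manifest_path(outdir, stage))


def _require_stage(outdir: Path, stage: str, needed_by: str) -> dict:
    p = _manifest_path(outdir, stage)
    if not p.exists():
        raise PipelineError(
            f"stage '{needed_by}' needs the outputs of stage '{stage}': "
            f"run `spinescan {stage}` first (missing {p})"
        )
    return json.loads(p.read_text())


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_simulate(cfg: RunConfig) -> Path:
    """Simulate every sample of the study and write the scan datasets."""
    outdir = Path(cfg.outdir)
    beam = cfg.beam_geometry()
    noise = cfg.noise_config()
    sc = cfg.scan
    outputs = []
    for sample in cfg.samples():
        phantom = BonePhantom(**sample["phantom"])
        rng = np.random.default_rng(sample["scan_seed"])
        scan = default_scan(
            radius_um=phantom.radius_um,
            step_um=sc.get("step_um", 2.0),
            margin_um=sc.get("margin_um", 8.0),
            n_omega=sc.get("n_omega", 18),
            beam_size_um=sc.get("beam_size_um", 4.0),
            seed=sample["scan_seed"],
        )
        bound = sc.get("drift_bound_steps", 2.0)
        if bound > 0:
            scan.drift_px = random_drift(scan.n_omega, rng, bound)
        ds = simulate_scan(phantom, beam, scan, noise, seed=sample["scan_seed"])
        d = io.save_dataset(ds, outdir / "datasets" / sample["sample"])
        io.save_json(sample, d / "sample.json")
        outputs.append(str(d))
    _write_manifest(outdir, "simulate", cfg, [], outputs)
    return outdir


def run_reduce(cfg: RunConfig) -> Path:
    """Reduce frames to d-spacing tables, element sinograms and (optionally)
    per-point orientation fits."""
    outdir = Path(cfg.outdir)
    man = _require_stage(outdir, "simulate", "reduce")
    outputs = []
    for ds_dir in man["outputs"]:
        ds_dir = Path(ds_dir)
        ds = io.load_dataset(ds_dir)
        red_dir = outdir / "reduction" / ds_dir.name
        red_dir.mkdir(parents=True, exist_ok=True)

        table = reduce_scan(ds)
        table.to_csv(red_dir / "reduction.csv", index=False)
        outputs.append(str(red_dir / "reduction.csv"))

        maps = xrf.build_maps(ds)
        for el, sino in maps.items():
            io.save_sinogram(sino, red_dir / f"sino_{el}")
            outputs.append(str(red_dir / f"sino_{el}.csv"))

        d_sino = strain.d_spacing_sinogram(
            table, ds.scan.omega_deg, ds.scan.x_positions_um
        )
        io.save_sinogram(d_sino, red_dir / "sino_d")
        outputs.append(str(red_dir / "sino_d.csv"))

        if cfg.analysis.get("orientation", True):
            fits = []
            for iw in range(ds.n_omega):
                row = []
                for ix in range(ds.n_x):
                    azi = orientation.integrate_sectors(ds.frame(iw, ix))
                    valid_d = bool(d_sino.mask[iw, ix])
                    row.append(orientation.fit_orientation(azi) if valid_d else None)
                fits.append(row)
            ang, dod = orientation.orientation_sinogram(
                fits, ds.scan.omega_deg, ds.scan.x_positions_um
            )
            io.save_sinogram(ang, red_dir / "sino_orientation")
            io.save_sinogram(dod, red_dir / "sino_dod")
            outputs.append(str(red_dir / "sino_orientation.csv"))
            outputs.append(str(red_dir / "sino_dod.csv"))
    _write_manifest(outdir, "reduce", cfg, man["outputs"], outputs)
    return outdir


def run_tomo(cfg: RunConfig) -> Path:
    """Sr-based drift correction, background normalization, back-projection."""
    outdir = Path(cfg.outdir)
    man = _require_stage(outdir, "reduce", "tomo")
    filtered = cfg.analysis.get("filtered_bp", True)
    outputs = []
    red_root = outdir / "reduction"
    for red_dir in sorted(p for p in red_root.iterdir() if p.is_dir()):
        tomo_dir = outdir / "tomo" / red_dir.name
        tomo_dir.mkdir(parents=True, exist_ok=True)
        sr = io.load_sinogram(red_dir / "sino_Sr.csv", "Sr")
        drift = tomo.estimate_drift(sr)
        io.save_json({
            "shifts_px": drift.shifts_px,
            "reference_center": drift.reference_center,
            "method": drift.method,
            "interpolated": drift.interpolated.tolist(),
        }, tomo_dir / "drift.json")
        outputs.append(str(tomo_dir / "drift.json"))
        for name in ("Sr", "Ca", "Zn", "elastic", "d", "orientation", "dod"):
            src = red_dir / f"sino_{name}.csv"
            if not src.exists():
                continue
            sino = io.load_sinogram(src, name)
            corr = tomo.apply_shifts(sino, drift)
            io.save_sinogram(corr, tomo_dir / f"sino_{name}_corr")
            outputs.append(str(tomo_dir / f"sino_{name}_corr.csv"))
            if name in ("Sr", "Ca", "Zn", "elastic"):
                norm = tomo.normalize_background(corr)
                img, _ = tomo.backproject(norm, filtered=filtered)
                tifffile.imwrite(
                    tomo_dir / f"map_{name}.tif", img.astype(np.float32)
                )
                outputs.append(str(tomo_dir / f"map_{name}.tif"))
    _write_manifest(outdir, "tomo", cfg, man["outputs"], outputs)
    return outdir


def run_strain(cfg: RunConfig) -> Path:
    """Per-sample strain estimates, group comparison, figures."""
    outdir = Path(cfg.outdir)
    _require_stage(outdir, "tomo", "strain")
    ana = cfg.analysis
    deproj = strain.PARABOLIC_DEPROJECTION if ana.get("deprojection", True) else 1.0
    strain_dir = outdir / "strain"
    strain_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    rows = []
    groups_apparent: dict[str, list[float]] = {}
    for ds_dir in sorted((outdir / "tomo").iterdir()):
        if not ds_dir.is_dir():
            continue
        sample = json.loads(
            (outdir / "datasets" / ds_dir.name / "sample.json").read_text()
        )
        sino = io.load_sinogram(ds_dir / "sino_d_corr.csv", "d_A")
        profiles, dropped = strain.normalize_width(sino)
        fits = [
            strain.fit_trend(p, model=ana.get("trend_model", "quadratic"),
                             robust=ana.get("robust", False))
            for p in profiles
        ]
        res = strain.aggregate_sample(fits, deproj, dropped)
        io.save_json({
            "sample": ds_dir.name,
            "species": sample["species"],
            "sample_strain_pct": res.sample_strain_pct,
            "sample_sd_pct": res.sample_sd_pct,
            "edge_strain_pct": res.edge_strain_pct,
            "deprojection_factor": res.deprojection_factor,
            "d_center_A": res.d_center_A,
            "n_angles": res.n_angles,
            "dropped_rows": res.dropped_rows,
            "per_angle_strain_pct": res.per_angle_strain_pct,
            "trend_model": ana.get("trend_model", "quadratic"),
        }, strain_dir / f"{ds_dir.name}.json")
        outputs.append(str(strain_dir / f"{ds_dir.name}.json"))
        plots.plot_normalized_trends(
            profiles, fits, strain_dir / f"{ds_dir.name}_trends.png"
        )
        rows.append({
            "sample": ds_dir.name, "species": sample["species"],
            "apparent_strain_pct": res.sample_strain_pct,
            "edge_strain_pct": res.edge_strain_pct,
            "sd_pct": res.sample_sd_pct, "n_angles": res.n_angles,
        })
        groups_apparent.setdefault(sample["species"], []).append(
            res.sample_strain_pct
        )
    table = pd.DataFrame(rows)
    table.to_csv(strain_dir / "samples.csv", index=False)
    outputs.append(str(strain_dir / "samples.csv"))

    if len(groups_apparent) == 2 and all(
        len(v) >= 3 for v in groups_apparent.values()
    ):
        (name_a, vals_a), (name_b, vals_b) = sorted(groups_apparent.items())
        comp = strain.compare_groups(vals_a, vals_b,
                                     paired=ana.get("paired", False))
        io.save_json({
            "group_a": name_a, "group_b": name_b, **comp.__dict__,
        }, strain_dir / "comparison.json")
        outputs.append(str(strain_dir / "comparison.json"))
    plots.plot_strain_boxplot(groups_apparent, strain_dir / "boxplot.png")
    _write_manifest(outdir, "strain", cfg, [], outputs)
    return outdir


def run_all(cfg: RunConfig) -> Path:
    run_simulate(cfg)
    run_reduce(cfg)
    run_tomo(cfg)
    return run_strain(cfg)
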