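# spinescan

Scanning X-ray diffraction / fluorescence (XRD/XRF) tomography analysis of
µm-scale bone samples — built around the question of how fish spine bones
carry **compressive residual strain** in their apatite nanocrystals.

Small teleost spines (~35–55 µm diameter cylinders of mineralized collagen)
are raster-scanned with a focused synchrotron beam: at each lateral position
*x* and rotation angle ω a 2D diffraction frame and an XRF energy spectrum
are recorded. From these, `spinescan` quantifies

* the apatite **c-lattice parameter** ("d-spacing", ≈ 6.88 Å) from a Voigt
  fit of the azimuthally integrated 002 Debye ring and Bragg's law
  *d = n·λ / (2 sin θ)* (the 002 plane spacing is c/2),
* **crystal orientation and degree of preferred orientation (DoD)** from a
  double-Gaussian fit of the 002 intensity over 36 azimuthal sectors (fiber
  texture gives two lobes exactly 180° apart),
* **elemental sinograms and maps** (Ca, Sr, Zn Kα windows, plus an elastic
  scatter channel) with Sr-based cross-correlation correction of rotation
  stage drift and (optionally filtered) back-projection,
* the **apparent residual strain** per sample,
  ε = (d_edge − d_center) / d_center, from width-normalized d-spacing
  sinograms with a per-angle regression — compression at the bone flanks
  shows up as ε < 0 (on the order of −0.1%),
* a rank-based **two-species group comparison** of the strain values.

Because real beamline data for this kind of experiment is rarely deposited,
the package ships a first-class **forward simulator**: a parametric bone
phantom (radial lattice-strain profile, fiber texture, Ca/Sr/Zn content with
a Zn-enriched outer rim and Ca self-absorption, stage drift, counting noise)
renders physically consistent detector frames and XRF spectra, so every
stage of the inference chain is testable by parameter recovery.

## Worked example

Simulate one "medaka-like" sample (injected local edge strain −0.10%,
per-angle stage drift up to ±2 steps, Poisson noise), reduce every frame,
correct drift from the Sr sinogram and estimate the strain:

```python
import numpy as np
from spinescan import (BeamGeometry, BonePhantom, NoiseConfig, default_scan,
                       random_drift, simulate_scan, reduce_scan,
                       d_spacing_sinogram, strain_from_sinogram,
                       estimate_drift, apply_shifts, build_maps, ElementWindow)

beam = BeamGeometry()                      # 18 keV, 002 ring mid-detector
phantom = BonePhantom(strain_edge=-0.001)  # -0.1% lattice deficit at the flanks
scan = default_scan(radius_um=phantom.radius_um, seed=11)
scan.drift_px = random_drift(scan.n_omega, np.random.default_rng(11))

dataset = simulate_scan(phantom, beam, scan, NoiseConfig(), seed=11)
table = reduce_scan(dataset)               # Voigt fit + Bragg per (x, ω) point
sino = d_spacing_sinogram(table, scan.omega_deg, scan.x_positions_um)
sr = build_maps(dataset, {"Sr": ElementWindow.default("Sr")}, elastic=False)["Sr"]
result = strain_from_sinogram(apply_shifts(sino, estimate_drift(sr)))
```

Output printed by this script (seed 11):

```
002 ring position        : 11.492 deg 2-theta
valid d-spacing points   : 422 / 558
d at sample center       : 6.8781 A
apparent strain          : -0.058 +/- 0.004 %
deprojected edge strain  : -0.087 %   (injected -0.100 %)
max drift residual       : 0.05 px
```

Reading the numbers: the 002 ring sits inside the expected 11.4–11.7° 2θ
window for apatite at 18 keV; points whose chord misses the mineral are
invalid by design. The *apparent* strain (−0.058%) is the raw projected
center-to-edge contrast — every measurement is a beam-path average through
the cylinder, which dilutes a parabolic radial profile by a factor 2/3 — and
the deprojected estimate (× 3/2) recovers the injected local edge strain
within the expected spread. Drift estimated purely from the Sr channel is
accurate to a few hundredths of a scan step.

A full two-species study (3 phantoms per species by default) runs from the
command line, one subcommand per stage:

```bash
spinescan simulate -c run.yaml --seed 17 --outdir runs/demo
spinescan reduce   -c run.yaml --seed 17 --outdir runs/demo
spinescan tomo     -c run.yaml --seed 17 --outdir runs/demo
spinescan strain   -c run.yaml --seed 17 --outdir runs/demo   # or: spinescan all
```

which writes reduction tables (CSV), drift-corrected sinograms (CSV+TIFF),
back-projected element maps, per-sample strain JSON, the species comparison
(exact rank-sum) and boxplot/trend figures, each stage with a manifest.

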