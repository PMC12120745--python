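# Methods

## Measurement model

A bone cross-section is modelled as a radially symmetric cylinder of
carbonated apatite. The beam (default 4 × 4 µm², 18 keV) crosses it at
lateral offset *x* while the sample rotates in ~10° increments over 180°.
Per scan point the forward model renders:

**Diffraction frame.** The 002 Debye ring is placed at the Bragg angle of
the *material-weighted mean* c-lattice along the beam chord,
2θ = 2·asin(n·λ/c̄). The radial ring profile is a true Voigt
(σ = 0.12°, γ = 0.06° by default — nanocrystalline peak widths so the ring
spans several detector pixels); azimuthal intensity is an isotropic floor
plus two opposite von-Mises lobes at the fiber azimuth, with the lobe area
fraction equal to the phantom's degree of preferred orientation
(`dod_true`). Diffuse low-angle scatter scales with the chord length, a flat
detector floor is added, and Poisson noise is applied per pixel. The default
exposure (`ring_counts = 1.2e6` photons for a full center chord) puts the
peak-pixel signal-to-noise near 50, i.e. visually clean 1D profiles.

**XRF spectrum.** Gaussian Kα peaks (detector resolution σ = 0.10 keV) for
Ca (3.691 keV), Zn (8.639 keV) and Sr (14.165 keV), with areas proportional
to the chord integral of each element's radial concentration profile. A line
is only emitted when the beam energy exceeds the element's K edge — a
13 keV scan therefore contains no Sr signal. Ca is additionally attenuated
by exp(−µ·ℓ) along the exit path toward the fluorescence detector
(µ = 0.04 µm⁻¹ by default), producing the characteristic self-absorption
gradient; Sr is treated as dilute and absorption-free, which is exactly the
property the drift correction relies on.

**Phantom fields.** The local lattice parameter is
d(r) = c_center·(1 + s·(r/R)²) for the default parabolic profile (linear and
piecewise-flat variants exist for robustness checks), so d(0) = c_center and
(d(R) − d(0))/d(0) = `strain_edge` exactly. Mineral density ramps from 1 to
0 across a transition zone (default 1 µm) at the surface; Ca and Sr follow
the mineral, Zn is a Gaussian rim centered on the outer surface
(σ = half the transition zone) plus a small bulk level. Stage drift is a
per-angle lateral offset, integer + fractional, bounded by ±2 scan steps.

## Reduction choices

* **Azimuthal integration** bins pixels by their exact 2θ (2000 bins over a
  ±2° window around the nominal apatite ring position for the configured
  energy) after dividing by the per-pixel (2θ, χ) Jacobian. Without this
  solid-angle correction the ~cos³2θ/tan2θ intensity falloff across the
  peak window biases fitted centers by ≈2 millidegrees (≈1.6 × 10⁻⁴ in d) —
  with it, noiseless round-trip errors are ~2 × 10⁻⁵.
* **Peak fitting** is a true Voigt via the complex error function
  (`scipy.special.voigt_profile`) with a jointly fitted linear background.
  Fits never raise; they are flagged not-ok when the solver fails, the
  center leaves the window, the signal-to-noise is below 5, or the Voigt
  FWHM is degenerate (narrower than 3 bins or wider than 75% of the fit
  window — the latter two catch background-only frames masquerading as
  peaks).
* **Orientation** integrates the ring over 36 sectors of 10°; the per-sector
  background is the unweighted mean of two flanking 2θ bands so linear
  background trends cancel. The double-Gaussian lobe fit constrains the two
  centers to be 180° apart (Friedel symmetry); a free-separation mode exists
  for diagnostics. DoD = A_lobes/(A_lobes + A_iso) with A_lobes the analytic
  Gaussian areas and A_iso the baseline over 360°; with non-negativity
  bounds on baseline and amplitudes this estimator is confined to [0, 1] and
  calibrates against the generator's `dod_true` to better than ±0.01 at
  default noise (the Gaussian-vs-von-Mises shape mismatch is negligible at
  18° lobe width). Whether the original DoD was a lobe-area fraction or a
  Herman-type parameter is not derivable from published material; the
  lobe-area fraction is this package's documented choice.
* **Drift correction** aligns Sr sinogram rows by cross-correlation against
  a mean-row template refined over two passes, with parabolic sub-pixel
  interpolation of the correlation peak; the global constant is anchored by
  placing the aligned template's center of mass on the grid center. Rows
  without signal inherit interpolated shifts and are flagged. Because the
  correlation of a profile with itself is symmetric, integer drifts on
  noiseless data are recovered exactly; fractional drifts recover to
  ≲0.1 px at default counting statistics. Shifts are applied to all
  co-acquired sinograms by linear interpolation (NaN-poisoning preserves
  masks); an integer mode exists for exactness tests.
* **Back-projection** wraps `skimage.transform.iradon`; ramp-filtered by
  default for element maps, unfiltered as an option. Pixels outside the
  inscribed circle are masked.
* **Strain.** Each sinogram row's valid extent is rescaled to 0–100% of the
  bone width (rows with <5 valid points are dropped and counted); a
  quadratic is fitted per row (robust Tukey-reweighted variant available)
  and evaluated at 0/50/100%. d₀ is the *fitted* value at 50%, not the raw
  center pixel. Per angle the two flank strains are averaged; the sample
  value is the mean ± SD over angles (spreads across angles, slices and
  samples are all computable and labeled — published per-sample spreads do
  not disambiguate which was meant).

## Projection dilution and the deprojected estimate

Every measured d is a chord average. For the parabolic profile the path mean
of (r/R)² at impact parameter b is (b² + (R² − b²)/3)/R² — 1/3 at the center,
1 at the tangent edge — so the *apparent* center-to-edge contrast is exactly
2/3 of the local edge strain. `StrainResult` therefore carries both numbers:
`sample_strain_pct` (the apparent strain, the quantity a projected
measurement reports) and `edge_strain_pct` = 3/2 × apparent (the model-based
estimate of the local edge strain, used for parameter recovery). Two residual
biases remain in the deprojected value: the outermost valid chord sits about
half a scan step inside the true tangent radius (≈ −9% on the recovered
magnitude at 2 µm steps on a 22 µm radius), and beam-width averaging smooths
the profile slightly. Recovery across injected strains of 0 to −0.15% stays
within ±0.02 percentage points and is linear (R² > 0.99).

## Group comparison

`compare_groups` defaults to the exact two-sided Wilcoxon rank-sum
(Mann-Whitney) for unpaired species groups; a signed-rank mode exists for
paired designs. Degenerate all-equal input returns p = 1 with a flag; ties
switch the p-value to the asymptotic method. Note on power: for two groups
at −0.0010 vs −0.0007 with SD 2 × 10⁻⁴ and n = 8 per group, the exact
rank-sum test's true power at α = 0.05 is ≈0.78 (measured by simulation with
5000 replicates; the paired signed-rank is ≈0.66 under arbitrary pairing) —
a study of that size detects the species difference in roughly three of four
repetitions, not reliably more.

## Synthetic-study scale and what it does not show

Default study conditions: cylinder radii drawn from 17.5–27.5 µm (35–55 µm
diameters), 2 µm scan steps with an 8 µm margin, 18 rotation angles over
180°, drift bounded by ±2 steps, per-sample strain variability
SD = 2 × 10⁻⁴ around the species means (−0.0010 "medaka-like", −0.0007
"zebrafish-like"), DoD 0.7, fiber azimuth 95°. High-resolution edge scans
use 300 nm steps at 13 keV. These sizes keep a full two-species study in the
minutes range on one core.

The simulator deliberately omits: wave optics and whole-powder-pattern
structure (a single 002 ring plus diffuse background), detector tilt and
calibration errors (geometry is taken as configured; no LaB₆ refinement),
3D structure (slices are independent), organ-level heterogeneity,
preferred-orientation variation along the chord, Compton/elastic energy
discrimination in the XRF spectrum, and absorption corrections in the
reconstruction. Passing recovery tests therefore demonstrates that the
*inference chain* is unbiased under the stated noise/drift model — not that
real-beamline systematics (tilt miscalibration, harmonics, beam damage)
are handled.

## Degenerate inputs and numerical conventions

Azimuth χ is signed, zero along the detector +horizontal axis, CCW positive,
range (−180°, 180°]; orientation is reported as a fiber axis mod 180°,
mapped to (−90°, 90°]. Empty integration sectors and background-only frames
yield flagged results, never exceptions; d-spacing values outside a
configurable plausibility window (6.5–7.2 Å) are masked before strain
analysis. All randomness flows through explicit seeds; identical
config + seed reproduces bit-identical datasets and reduction tables.
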