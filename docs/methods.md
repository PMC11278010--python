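# Methods

This note documents the models, conventions and numerical choices behind
`periscat`, and what the simulation-based tests do and do not demonstrate
about real beamline data.

## Geometry and reciprocal space

A flat detector normal to the beam is assumed throughout. Conversions are
exact at all angles: `2θ = atan(r/D)`, `q = (4π/λ) sin θ`, with
`λ [nm] = 1.239842 / E [keV]`. No small-angle approximation is used anywhere,
because the HAp (002) ring at 15 keV sits at 2θ ≈ 0.24 rad where
`tan(2θ)` and `2 sin θ` differ from 2θ by ~1 %. Azimuth is measured
counter-clockwise from the +column axis in the detector plane.

The detector model is idealized: pixel values sample the intensity at the
pixel center (no area integration, no point-spread function, no tilt).
Detector tilt is neither simulated nor refined; calibration adjusts beam
center and sample–detector distance only.

### Geometry calibration

Synthetic LaB6 frames (cubic lattice constant 0.415691 nm) provide
reference rings. Per ring, sector-wise Gaussian radial fits give ring
points; a Kasa circle fit per ring estimates the beam center, and the
distance is the least-squares match of measured radii against
`D·tan(2θ_ref)`. Two to three iterations converge from initial errors of
several percent in distance and several pixels in center; on noise-free
megapixel frames the round-trip error is ~10⁻⁶ relative (tested bounds:
0.1 % in distance, 0.1 px in center).

## Azimuthal integration

Plain histogram averaging in equal-width q bins with exact pixel
bookkeeping: every unmasked pixel lands in exactly one bin, so
pixel-count-weighted sector means recompose the full-circle mean to
floating-point accuracy (a tested identity). Per-bin uncertainty is the
standard error of the contributing pixel values. Each occupied bin reports
the *mean pixel q* as its abscissa rather than the geometric bin center;
on small detectors the in-bin q distribution is sparse and asymmetric, and
the mean-q abscissa removes the resulting sampling bias from downstream
peak fits. Empty bins carry NaN intensity and `n_pixels = 0`, never
zero-fill. Solid-angle and polarization corrections are not applied.

## Wide-angle stage: d-spacing and crystallite size

The (002) peak is fit with a Gaussian plus linear background (lmfit),
weighted by per-bin uncertainties when available so that reported
center/width uncertainties stay calibrated under counting noise (verified
by a 500-replicate coverage test). The default fit window is ±5 expected
FWHM around `2π/d_prior` with priors d = 0.344 nm, τ = 30 nm — a
reproducible automation of choosing a well-isolated peak.

Conventions that the field leaves ambiguous, fixed here and tested:

* β in the Scherrer equation `τ = Kλ/(β cos θ)` is the FWHM in radians on
  the **2θ axis**; the fitted q-width is converted by differencing the
  angles at the two half-maximum q positions (exact, not a derivative).
* K = 1.0 by default; configurable in (0.8, 1.2].
* No instrumental broadening is subtracted by default (the beamline
  resolution is not known); optional quadrature subtraction
  `β² = β_obs² − β_instr²` is available and can only increase τ.
* Bragg conversion uses `d = 2πn/q`; uncertainties propagate to first
  order from the fit covariance.

QC: records with failed fits, R² below 0.75, or centers at the window edge
are flagged (never silently zeroed); maps carry NaN at flagged points.

## Small-angle stage: T-parameter

For an ideal two-phase material the stack-of-cards platelet thickness is
`T = 4Φ(1−Φ)/σ_v`; its experimental realization is `T = (4/π)·Q/P` with
invariant `Q = ∫q²I dq` and Porod constant `P = lim q⁴I`. The estimator:

* **Porod fit** — weighted linear fit of `q⁴I` against `[1, q⁻²]` over the
  top 30 % of the q range (the `q⁻²` term absorbs the leading Porod
  deviation), with an optional flat incoherent background term (`+B·q⁴`)
  intended for noisy data and off by default.
* **Invariant** — trapezoid over the measured range, extended below the
  first bin by a q² rise of the Kratky curve (continuity) and above the
  last bin by the fitted tail `P/q + c/(3q³)`.
* **Fit quality** — fraction of Kratky-curve variance explained over the
  Porod range, clipped to [0, 1]; QC threshold 0.75 by default, matching
  the fit-quality floor used for bone data where the collagen SAXS signal
  overlays the mineral signal. No collagen correction is attempted; the
  flag is the only handle.

On noise-free synthetic profiles with `q ∈ [0.01, 5] nm⁻¹` (q_max·T = 15)
the estimator is accurate to ~0.5 % across stack-disorder settings;
its documented accuracy bound is 3 %. A warning is raised when
`q_max·T < 8` (Porod regime barely reached).

## Spatial gradients

Distances from the bone-to-implant interface come either from a half-plane
descriptor or from an exact Euclidean distance transform of a user-supplied
interface mask (validated against a brute-force all-pairs oracle);
implant-interior points are NaN-flagged and excluded. Distance profiles
report per-bin mean and t-based 95 % CI over points (between-point
variability). Gradients are ordinary least squares on the raw per-point
records — not binned means — up to 0.8 mm by default, maximizing degrees of
freedom; the slope CI is `t_{0.975,n−2}` times the standard error, with
coverage verified at ≥ 93 % over 200 seeded noisy replicates.

## Indentation strain mapping

Per frame, ring points are the Gaussian radial peak positions of 36
azimuthal sectors mapped to Cartesian q-space; the ellipse is the direct
least-squares conic fit constrained to ellipses (generalized-eigenvalue
formulation, numerically centered and scaled). `ε = a/b ≤ 1` is enforced by
axis ordering; strain profiles report the deviation `1 − ε`, which grows
toward the tip.

Two numerical subtleties matter at the 10⁻⁵ level of ε:

* **Sector smearing** — pooling a sector averages the ring radius over its
  azimuth span, attenuating the elliptical (second-harmonic) modulation by
  `sin(w)/w` (w = sector width). The extracted radii are deconvolved by
  rescaling their fitted second harmonic; without this the ratio is biased
  toward circularity by ~1 % of (1 − ε).
* **Axis anticorrelation** — both semi-axes share the fitted harmonic
  amplitude, so their errors are anticorrelated (`cov(a,b) = −σ²/m` for m
  uniform sectors with point noise σ). The ε uncertainty therefore includes
  the covariance term on top of the independent-axis propagation
  `σ_ε² = (σ_a/b)² + (a σ_b/b²)² − 2a·cov/b³`; omitting it underestimates
  σ_ε by ~15 %. Per-axis σ comes from the radial point residuals with a
  5-dof correction, `σ_axis = σ_point·√(3/m)`.

With Poisson noise at 10⁴ peak counts, per-point ε is within 3σ of truth at
~99.8 % of points on a 36×36 grid, and z-scores have unit variance.

No registration between force steps is performed — each fixed-force scan is
self-contained by construction of the ratio. The tip position is metadata,
never inferred from images. Absolute strain or stress calibration and
contact mechanics are out of scope.

## The simulator: what it emulates and what it does not

Study conditions baked into the defaults: 15 keV scanning acquisitions
(1 Mpixel detector as the reference geometry), 1 mm × 0.3 mm regions at
27 µm steps (`floor(extent/step)+1` points per axis → 38 × 12), a 17 keV
indentation mode imaging 70 µm × 70 µm at 2 µm spacing (36 × 36) with
forces in [0, 2500] mN, and linear parameter gradients away from a planar
interface. Default field values are typical of peri-implant bone: d-spacing
0.3425 nm at the interface, crystallite size 35 nm, T-parameter 2.8 nm with
+0.3 nm/mm recovery toward cortical values.

The XRD frame model is a single (002) ring with a Gaussian radial profile
whose 2θ FWHM follows the Scherrer relation, optionally broadened in
quadrature by an instrumental term (default 0 — the beamline resolution is
unpublished, so it is a free parameter rather than a guess). Elliptical
distortion is applied in q-space with geometric-mean-preserving axes
(`a = q₀√ε`, `b = q₀/√ε`) and mapped back to pixels exactly. Poisson noise
acts on counts; a flat background of 2 % of the peak scale is included.

The SAXS model is a 1D random two-phase stack with Gamma-distributed layer
thicknesses (shape k, default 4), orientation-averaged (`1/q²`). Its
closed-form intensity satisfies `(4/π)Q/P = 2Φ(1−Φ)·period = T` exactly for
every k; k controls stacking disorder, with k = 1 the fully random
(Lorentzian) limit and larger k producing the broad Kratky maximum typical
of bone. Noise on 1D profiles is multiplicative Gaussian.

The strain field under the indenter decays exponentially with distance from
the tip (length 25 µm by default, ratio at the tip linear in force unless a
per-force table is given). This kernel is a simulation choice for
verifiability, not a physical claim; the force–displacement law is likewise
a configurable monotone power law (Hertz-like exponent 2/3).

Not simulated: collagen fibril diffraction (the main real-data confounder
of the T-parameter fit), texture/preferred orientation, HAp reflections
other than (002), detector point-spread, gas voids, tilt. Passing recovery
tests therefore demonstrates correctness of the estimators under the stated
forward models — not robustness to these real-data effects, of which the
collagen overlay is known to degrade Kratky fit quality to the QC floor.

## Problem sizes used in tests

Routine tests run on compact geometries (256–384 px detectors, few-point
scan grids) chosen so the ring remains well-sampled (≥ 1.7 px FWHM; below
that, sector fits develop pixel-phase systematics). The headline recovery
checks use the full 1 Mpixel reference geometry and the full 36 × 36
indentation grid. Determinism is end-to-end: every random draw descends
from an explicit seed, and identical configs re-execute to byte-identical
tables (the config hash, excluding the output directory, is embedded in
every CSV header and the run report).
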