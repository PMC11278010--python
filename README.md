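# periscat

Scanning SAXS/XRD analysis of bone ultrastructure around (degradable)
implants: from 2D detector frames to spatial maps and distance-resolved
gradients of lattice spacing, crystallite size and mineral platelet
thickness, plus relative-strain mapping of in situ nanoindentation series.

## The problem

When a magnesium-alloy screw degrades inside bone, Mg²⁺ ions can substitute
Ca²⁺ in the hydroxyapatite (HAp) lattice and the newly formed bone near the
interface may be less mature than cortical bone further away. Scanning
small-angle X-ray scattering (SAXS) and X-ray diffraction (XRD) with a
micro-focused synchrotron beam resolve these effects spatially: each scan
position yields a 2D scattering pattern from which three nanoscale
parameters are extracted and then analyzed as a function of distance from
the bone-to-implant interface. A companion in situ experiment presses a
nanoindenter into the bone at the interface while scanning, and maps the
elastic lattice strain under the tip.

## Models and statistics at the core

Per scan point, from the azimuthally integrated wide-angle profile I(q):

* **d-spacing** — the HAp (002) Bragg peak is fit with a Gaussian plus
  linear background; Bragg's law `n λ = 2 d sin θ` gives
  `d = 2 π n / q_center`.
* **Crystallite size** — the Scherrer equation `τ = K λ / (β cos θ)`,
  with β the fitted FWHM in radians on the 2θ axis and K = 1.
* **T-parameter** (mean mineral platelet thickness) — from the SAXS
  profile via the stack-of-cards model: `T = (4/π) · Q / P`, where
  `Q = ∫ q² I dq` is the scattering invariant (Kratky-plot area, with
  low-q and Porod-tail extrapolations) and `P = lim q⁴ I` the Porod
  constant.

Maps of these parameters are reduced to distance profiles (mean ± 95% CI,
t-based) and to straight-line gradients fitted up to 0.8 mm from the
interface, with 95% confidence intervals from the fit covariance.

For indentation scans, elastic strain turns each Debye–Scherrer ring into
an ellipse in reciprocal space. Ring points are located sector-by-sector
(Gaussian radial peak per azimuthal sector), a direct least-squares ellipse
is fitted, and the **relative strain** is `ε_relative = a/b` (semi-minor
over semi-major axis; 1 = unstrained), with uncertainty propagated from the
point-fit residuals. Because ε is relative *within* each frame, no
registration between force steps is needed.

A forward simulator (`periscat.simulate`) generates detector frames, scan
grids and indentation series with known ground truth — Scherrer-consistent
ring widths, an analytic two-phase lamellar stack whose invariants satisfy
`(4/π)·Q/P = T` exactly, elliptical ring distortion of prescribed axis
ratio, Poisson counting noise — so every stage of the pipeline is
verifiable by parameter recovery.

## Worked example

Simulate a 0.8 mm scan away from a planar interface with known gradients,
run the analysis, and fit the gradients:

```python
import numpy as np
from periscat import (SimulationConfig, GroundTruthField, ScanGrid,
                      simulate_scan_grid, map_ultrastructure, t_parameter_map,
                      fit_gradient)

cfg = SimulationConfig(energy_kev=15.0, detector_shape=(320, 320),
                       pixel_size_um=150.0, sample_detector_distance_mm=80.0,
                       noise=False, seed=1)
field = GroundTruthField(d_spacing_at_interface_nm=0.3415,
                         d_spacing_gradient_nm_per_mm=0.0025,
                         t_parameter_at_interface_nm=2.8,
                         t_parameter_gradient_nm_per_mm=0.3)
grid = ScanGrid(x_extent_mm=0.8, y_extent_mm=0.1, step_mm=0.1)
sim = simulate_scan_grid(field, grid, cfg,
                         saxs_q_grid=np.linspace(0.01, 5.0, 800))

records = map_ultrastructure(sim.frames, cfg.geometry())
profiles = {(x, y): p for (x, y), p in zip(
    map(tuple, sim.truth[["x_mm", "y_mm"]].to_numpy()), sim.saxs_profiles)}
records = t_parameter_map(profiles, records)
records["distance_mm"] = records["x_mm"]          # interface at x = 0

g_d = fit_gradient(records, "d_spacing_nm", max_distance_mm=0.8)
g_t = fit_gradient(records, "t_parameter_nm", max_distance_mm=0.8,
                   qc_col="t_qc_pass")
print(f"d-spacing gradient: {g_d.slope:+.4f} +/- {g_d.slope_ci95_half_width:.4f} nm/mm")
print(f"T-parameter gradient: {g_t.slope:+.4f} +/- {g_t.slope_ci95_half_width:.4f} nm/mm")
print(f"mean d-spacing: {records['d_spacing_nm'].mean():.4f} nm, "
      f"mean T: {records['t_parameter_nm'].mean():.3f} nm")
```

Output:

```
d-spacing gradient: +0.0025 +/- 0.0000 nm/mm
T-parameter gradient: +0.2860 +/- 0.0004 nm/mm
mean d-spacing: 0.3425 nm, mean T: 2.933 nm
```

The d-spacing gradient is recovered exactly (noise-free lattice parameters
are read off the ring position to ~10⁻⁶ relative); the T gradient comes
back at 0.286 nm/mm for a true 0.3 nm/mm because the Kratky estimator
carries a sub-percent, weakly T-dependent truncation bias — well inside its
documented 3 % accuracy. The mean d-spacing (0.3425 nm) is the ground-truth
field's mid-scan average.

The same workflows are scriptable from the shell via the `periscat` CLI
(`simulate-scan`, `simulate-indent`, `calibrate`, `scan`, `indent`), each
driven by a YAML config and writing CSV tables, float-TIFF maps, PNG
figures and a JSON run report. See `periscat --help`.

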