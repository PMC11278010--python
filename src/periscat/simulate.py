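"""Forward simulation of scanning SAXS/XRD acquisitions with known ground truth.

This module emulates the two acquisition modes of a scanning-beamline bone
study well enough that every downstream stage can be validated by parameter
recovery:

* 2D wide-angle detector frames containing the hydroxyapatite (002)
  Debye-Scherrer ring. The radial profile is Gaussian in 2-theta with FWHM
  given by the Scherrer relation ``beta = K lambda / (tau cos theta)`` (plus
  optional instrumental broadening in quadrature), and elastic lattice
  strain distorts the ring into an ellipse in q-space with a prescribed
  semi-minor/semi-major ratio.
* 1D small-angle profiles of the mineral/organic lamellar composite from an
  ideal two-phase stack-of-cards model, whose scattering invariant Q and
  Porod constant P satisfy ``(4/pi) Q / P = T`` (mean platelet thickness
  proxy) exactly.

Scan grids impose linear parameter gradients away from a synthetic
bone-to-implant interface; indentation series impose a strain field that
decays exponentially with distance from the indenter tip. All randomness is
Poisson counting noise (2D frames) or multiplicative Gaussian noise (1D
profiles), always under an explicit seed: identical configuration + seed
gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._fitting import FWHM_PER_SIGMA
from .frames import DetectorFrame
from .geometry import (ExperimentGeometry, two_theta_from_q, wavelength_nm)
from .reduction import RadialProfile

#: LaB6 cubic lattice constant (nm), NIST SRM 660-type calibrant.
LAB6_LATTICE_NM = 0.415691

#: Default LaB6 reflections used for synthetic calibrant frames.
LAB6_HKL = ((1, 0, 0), (1, 1, 0), (1, 1, 1), (2, 0, 0), (2, 1, 0))


@dataclass
class SimulationConfig:
    """Acquisition geometry and noise settings for simulated frames.

    Defaults mirror a 15 keV wide-angle scanning setup: ~1 Mpixel detector
    with 75 um pixels at 120 mm, which places the HAp (002) ring at
    ~393 px radius. ``exposure_scale`` is the expected peak count;
    ``background_fraction`` adds a flat baseline as a fraction of it.
    """

    energy_kev: float = 15.0
    detector_shape: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 75.0
    sample_detector_distance_mm: float = 120.0
    beam_center: Optional[tuple[float, float]] = None
    exposure_scale: float = 1.0e4
    background_fraction: float = 0.02
    noise: bool = True
    seed: int = 0
    scherrer_K: float = 1.0
    instrumental_fwhm_2theta: float = 0.0  # rad; beamline resolution, 0 = ideal

    def __post_init__(self) -> None:
        if self.energy_kev <= 0:
            raise ValueError("photon energy must be positive")
        if self.sample_detector_distance_mm <= 0:
            raise ValueError("sample-detector distance must be positive")
        self.detector_shape = tuple(int(n) for n in self.detector_shape)
        if self.beam_center is not None:
            self.beam_center = tuple(float(c) for c in self.beam_center)
        if self.beam_center is None:
            self.beam_center = ((self.detector_shape[0] - 1) / 2.0,
                                (self.detector_shape[1] - 1) / 2.0)
        nr, nc = self.detector_shape
        cr, cc = self.beam_center
        if not (-0.25 * nr <= cr <= 1.25 * nr and -0.25 * nc <= cc <= 1.25 * nc):
            raise ValueError("beam center far outside detector bounds")

    @property
    def wavelength(self) -> float:
        return wavelength_nm(self.energy_kev)

    def geometry(self) -> ExperimentGeometry:
        """The exact (ground-truth) geometry of this configuration."""
        return ExperimentGeometry(wavelength=self.wavelength,
                                  beam_center=tuple(self.beam_center),
                                  distance_mm=self.sample_detector_distance_mm,
                                  pixel_size_um=self.pixel_size_um)


# ---------------------------------------------------------------------------
# 2D diffraction frames
# ---------------------------------------------------------------------------

def _ring_model(config: SimulationConfig, q_ring: float, tau_nm: float,
                strain_ratio: float, orientation_rad: float) -> np.ndarray:
    """Noise-free counts image of one (elliptically distorted) powder ring."""
    geom = config.geometry()
    shape = config.detector_shape
    qmap = geom.q_map(shape)
    az = np.radians(geom.azimuth_map(shape))
    # Ellipse semi-axes in q-space with geometric mean q_ring: the semi-major
    # axis grows as the semi-minor shrinks (volume-conserving distortion),
    # and a/b equals strain_ratio.
    a = q_ring * math.sqrt(strain_ratio)
    b = q_ring / math.sqrt(strain_ratio)
    q_edge = geom.q_at_nearest_edge(shape)
    if b >= q_edge:
        raise ValueError(
            f"ring at q = {b:.3f} nm^-1 falls outside the detector; the "
            f"maximum fully-representable q for this geometry is "
            f"{q_edge:.3f} nm^-1")
    phi = az - orientation_rad
    q_c = a * b / np.sqrt((a * np.cos(phi)) ** 2 + (b * np.sin(phi)) ** 2)
    tt_c = two_theta_from_q(q_c, geom.wavelength)
    beta = config.scherrer_K * geom.wavelength / (tau_nm * np.cos(tt_c / 2.0))
    beta = np.sqrt(beta ** 2 + config.instrumental_fwhm_2theta ** 2)
    sigma_tt = beta / FWHM_PER_SIGMA
    tt = two_theta_from_q(qmap, geom.wavelength)
    return config.exposure_scale * np.exp(-0.5 * ((tt - tt_c) / sigma_tt) ** 2)


def simulate_xrd_frame(config: SimulationConfig, d_nm: float, tau_nm: float,
                       strain_ratio: float = 1.0,
                       orientation_rad: float = 0.0,
                       seed: Optional[int] = None,
                       metadata: Optional[dict] = None) -> DetectorFrame:
    """Simulate one detector frame with a single (002)-like powder ring.

    The ring sits, after q-conversion, on an ellipse in reciprocal space
    with semi-minor/semi-major ratio ``strain_ratio`` (1 = unstrained
    circle, geometric-mean q = 2 pi / d) and has a Gaussian radial profile
    whose 2-theta FWHM follows the Scherrer relation for crystallite size
    ``tau_nm`` (shape factor ``config.scherrer_K``). Poisson noise is
    applied iff ``config.noise``; the generating ground truth is recorded
    in the frame metadata.
    """
    if d_nm <= 0 or tau_nm <= 0:
        raise ValueError("d-spacing and crystallite size must be positive")
    if not 0.0 < strain_ratio <= 1.0:
        raise ValueError("strain_ratio must be in (0, 1]")
    q_ring = 2.0 * np.pi / d_nm
    model = _ring_model(config, q_ring, tau_nm, strain_ratio, orientation_rad)
    model = model + config.background_fraction * config.exposure_scale
    if config.noise:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        counts = rng.poisson(model).astype(np.float64)
    else:
        counts = model
    meta = {"truth": {"d_nm": d_nm, "tau_nm": tau_nm,
                      "strain_ratio": strain_ratio,
                      "orientation_rad": orientation_rad,
                      "q_ring": q_ring},
            "energy_kev": config.energy_kev, "exposure_s": 1.0}
    if metadata:
        meta.update(metadata)
    return DetectorFrame(counts=counts, metadata=meta)


def lab6_spacings(config: SimulationConfig,
                  hkl: Sequence[tuple[int, int, int]] = LAB6_HKL,
                  margin: float = 0.98) -> list[float]:
    """LaB6 lattice spacings whose full rings fit on the configured detector."""
    geom = config.geometry()
    q_edge = geom.q_at_nearest_edge(config.detector_shape) * margin
    out = []
    for h, k, l in hkl:
        d = LAB6_LATTICE_NM / math.sqrt(h * h + k * k + l * l)
        if 2.0 * np.pi / d < q_edge:
            out.append(d)
    return out


def simulate_lab6_frame(config: SimulationConfig, tau_nm: float = 60.0,
                        seed: Optional[int] = None,
                        ) -> tuple[DetectorFrame, list[float]]:
    """Synthetic LaB6 calibrant frame (all rings that fit the detector).

    Returns the frame and the list of simulated lattice spacings (nm),
    largest first, for use as calibration references.
    """
    spacings = lab6_spacings(config)
    if len(spacings) < 2:
        raise ValueError("geometry leaves fewer than 2 LaB6 rings on the detector")
    model = np.zeros(config.detector_shape, dtype=float)
    for d in spacings:
        model += _ring_model(config, 2.0 * np.pi / d, tau_nm, 1.0, 0.0)
    model += config.background_fraction * config.exposure_scale
    if config.noise:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        counts = rng.poisson(model).astype(np.float64)
    else:
        counts = model
    meta = {"truth": {"lab6_spacings_nm": list(spacings), "tau_nm": tau_nm},
            "energy_kev": config.energy_kev}
    return DetectorFrame(counts=counts, metadata=meta), spacings


# ---------------------------------------------------------------------------
# 1D lamellar SAXS profiles (stack-of-cards model)
# ---------------------------------------------------------------------------

def lamellar_stack_intensity(q, t_parameter: float, volume_fraction: float,
                             shape_k: float = 4.0, scale: float = 1.0):
    """Analytic isotropic intensity of an ideal two-phase lamellar stack.

    The structure is a 1D random stack of alternating mineral and organic
    layers with Gamma-distributed thicknesses (shape ``shape_k``; ``k = 1``
    is the fully random exponential limit, large ``k`` approaches a regular
    stack). Mean thicknesses are fixed by the target T-parameter and mineral
    volume fraction through ``T = 2 phi (1 - phi) * period``. Using the
    characteristic functions ``f = E[exp(i q t)]`` of the two thickness
    distributions, the 1D stack intensity is

        I1(q)  proportional to  Re[(1 - f_m)(1 - f_g) / (1 - f_m f_g)] / q^2

    and isotropic orientation averaging contributes a further 1/q^2. The
    Porod constant is ``P = scale`` and the invariant ``Q = scale *
    pi * T / 4`` for every ``shape_k``, so ``(4/pi) Q / P = T`` exactly.
    """
    if t_parameter <= 0:
        raise ValueError("t_parameter must be positive")
    if not 0.0 < volume_fraction < 1.0:
        raise ValueError("volume_fraction must lie strictly in (0, 1)")
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q grid must be strictly positive")
    period = t_parameter / (2.0 * volume_fraction * (1.0 - volume_fraction))
    t_m = volume_fraction * period
    t_g = (1.0 - volume_fraction) * period
    f_m = (1.0 - 1j * q * t_m / shape_k) ** (-shape_k)
    f_g = (1.0 - 1j * q * t_g / shape_k) ** (-shape_k)
    G = np.real((1.0 - f_m) * (1.0 - f_g) / (1.0 - f_m * f_g))
    return scale * G / q ** 4


def lamellar_invariants(t_parameter: float, volume_fraction: float,
                        scale: float = 1.0) -> tuple[float, float]:
    """Exact (invariant Q, Porod constant P) of the lamellar stack model."""
    del volume_fraction  # fixed by T through the period; Q/P depends on T only
    return scale * np.pi * t_parameter / 4.0, scale


def simulate_saxs_profile(t_parameter: float, volume_fraction: float,
                          q_grid, noise_scale: float = 0.0, seed: int = 0,
                          shape_k: float = 4.0, scale: float = 1.0,
                          ) -> RadialProfile:
    """Simulate one azimuthally-averaged SAXS profile of the mineral stack.

    ``noise_scale`` applies multiplicative Gaussian noise (relative standard
    deviation per bin); 0 gives the noise-free analytic curve. The q grid
    must reach well into the Porod regime (``q_max * T >= 8``) so that the
    invariant and Porod constant are recoverable.
    """
    q = np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or np.any(np.diff(q) <= 0) or np.any(q <= 0):
        raise ValueError("q_grid must be 1D, positive and strictly increasing")
    if q[-1] * t_parameter < 8.0:
        raise ValueError(
            f"q_grid too short to resolve the Kratky/Porod regime: "
            f"q_max * T = {q[-1] * t_parameter:.2f}, need >= 8")
    intensity = lamellar_stack_intensity(q, t_parameter, volume_fraction,
                                         shape_k=shape_k, scale=scale)
    sigma = noise_scale * intensity
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (1.0 + noise_scale * rng.standard_normal(q.shape))
    return RadialProfile(q=q, intensity=intensity, sigma=sigma)


# ---------------------------------------------------------------------------
# scan grids with spatial ground-truth gradients
# ---------------------------------------------------------------------------

def default_strain_at_tip(force_mn: float) -> float:
    """Default tip strain-ratio law: linear in force, 0.99 at 2500 mN."""
    return 1.0 - 4.0e-6 * force_mn


@dataclass
class GroundTruthField:
    """Spatial ground truth: linear gradients away from a planar interface.

    Parameters at distance x (mm) from the bone-to-implant interface are
    ``value_at_interface + gradient * x``; the implant occupies
    ``x < interface_x_mm``. For indentation runs, ``strain_ratio_at_tip``
    maps applied force (mN) to the ellipse axis ratio directly under the
    tip, and the ratio relaxes back to 1 with an exponential kernel of
    length ``strain_decay_um`` (a simulation choice, not a physical claim).
    """

    d_spacing_at_interface_nm: float = 0.3425
    d_spacing_gradient_nm_per_mm: float = 0.002
    crystallite_size_nm: float = 35.0
    crystallite_gradient_nm_per_mm: float = 0.0
    t_parameter_at_interface_nm: float = 2.8
    t_parameter_gradient_nm_per_mm: float = 0.3
    mineral_volume_fraction: float = 0.5
    interface_x_mm: float = 0.0
    strain_ratio_at_tip: Union[dict, Callable[[float], float], None] = None
    strain_decay_um: float = 25.0

    def __post_init__(self) -> None:
        if min(self.d_spacing_at_interface_nm, self.crystallite_size_nm,
               self.t_parameter_at_interface_nm, self.strain_decay_um) <= 0:
            raise ValueError("thicknesses, spacings and decay length must be > 0")
        if not 0.0 < self.mineral_volume_fraction < 1.0:
            raise ValueError("mineral volume fraction must lie in (0, 1)")

    def tip_strain_ratio(self, force_mn: float) -> float:
        if callable(self.strain_ratio_at_tip):
            r = float(self.strain_ratio_at_tip(force_mn))
        elif isinstance(self.strain_ratio_at_tip, dict):
            r = float(self.strain_ratio_at_tip[force_mn])
        else:
            r = default_strain_at_tip(force_mn)
        if not 0.0 < r <= 1.0:
            raise ValueError(f"strain ratio {r} outside (0, 1]")
        return r

    def at_distance(self, distance_mm) -> dict:
        """Ground-truth (d, tau, T) at given distance(s) from the interface."""
        x = np.asarray(distance_mm, dtype=float)
        return {
            "d_nm": self.d_spacing_at_interface_nm
                    + self.d_spacing_gradient_nm_per_mm * x,
            "tau_nm": self.crystallite_size_nm
                      + self.crystallite_gradient_nm_per_mm * x,
            "t_nm": self.t_parameter_at_interface_nm
                    + self.t_parameter_gradient_nm_per_mm * x,
        }


@dataclass
class ScanGrid:
    """Rectangular scan grid: extents and step, physical (mm) coordinates.

    The number of points per axis is ``floor(extent / step) + 1`` (points at
    both ends of each axis whenever extent is a multiple of the step); the
    grid origin (first point) sits at ``(x0_mm, y0_mm)``.
    """

    x_extent_mm: float = 1.0
    y_extent_mm: float = 0.3
    step_mm: float = 0.027
    x0_mm: float = 0.0
    y0_mm: float = 0.0

    @property
    def n_x(self) -> int:
        return int(math.floor(self.x_extent_mm / self.step_mm + 1e-9)) + 1

    @property
    def n_y(self) -> int:
        return int(math.floor(self.y_extent_mm / self.step_mm + 1e-9)) + 1

    def positions(self) -> pd.DataFrame:
        """All scan positions, row-major over (y, x), in mm."""
        xs = self.x0_mm + self.step_mm * np.arange(self.n_x)
        ys = self.y0_mm + self.step_mm * np.arange(self.n_y)
        gy, gx = np.meshgrid(ys, xs, indexing="ij")
        return pd.DataFrame({"x_mm": gx.ravel(), "y_mm": gy.ravel()})


def ground_truth_table(field: GroundTruthField, grid: ScanGrid) -> pd.DataFrame:
    """Per-scan-point ground-truth sidecar table (no frames simulated)."""
    pos = grid.positions()
    dist = pos["x_mm"].to_numpy() - field.interface_x_mm
    in_implant = dist < 0
    truth = field.at_distance(np.clip(dist, 0.0, None))
    out = pos.copy()
    out["distance_mm"] = dist
    out["in_implant"] = in_implant
    out["d_nm"] = np.where(in_implant, np.nan, truth["d_nm"])
    out["tau_nm"] = np.where(in_implant, np.nan, truth["tau_nm"])
    out["t_nm"] = np.where(in_implant, np.nan, truth["t_nm"])
    return out


@dataclass
class ScanSimulation:
    """Frames + SAXS profiles + ground truth for one simulated scan."""

    frames: list
    truth: pd.DataFrame
    saxs_profiles: Optional[list] = None
    config: Optional[SimulationConfig] = None


def simulate_scan_grid(field: GroundTruthField, grid: ScanGrid,
                       config: SimulationConfig,
                       saxs_q_grid=None,
                       saxs_noise_scale: float = 0.0) -> ScanSimulation:
    """Simulate one scan: an XRD frame per point, with linear gradients.

    Implant-interior points (distance < 0) get background-only frames and
    NaN ground truth. When ``saxs_q_grid`` is given, a lamellar SAXS profile
    per point is generated alongside (from the same ground-truth T field).
    """
    truth = ground_truth_table(field, grid)
    if not ((truth["distance_mm"] >= 0).any()):
        raise ValueError("scan grid lies entirely inside the implant")
    children = np.random.SeedSequence(config.seed).spawn(2 * len(truth))
    frames = []
    saxs = [] if saxs_q_grid is not None else None
    for i, row in truth.iterrows():
        meta = {"x_mm": float(row["x_mm"]), "y_mm": float(row["y_mm"])}
        seed_xrd = int(children[2 * i].generate_state(1)[0] % (2 ** 31))
        if row["in_implant"]:
            model = np.full(config.detector_shape,
                            config.background_fraction * config.exposure_scale)
            if config.noise:
                rng = np.random.default_rng(seed_xrd)
                model = rng.poisson(model).astype(np.float64)
            frames.append(DetectorFrame(counts=model,
                                        metadata={**meta, "truth": {"in_implant": True}}))
        else:
            frames.append(simulate_xrd_frame(
                config, d_nm=float(row["d_nm"]), tau_nm=float(row["tau_nm"]),
                seed=seed_xrd, metadata=meta))
        if saxs is not None:
            seed_saxs = int(children[2 * i + 1].generate_state(1)[0] % (2 ** 31))
            t_nm = row["t_nm"] if not row["in_implant"] else field.t_parameter_at_interface_nm
            prof = simulate_saxs_profile(
                float(t_nm), field.mineral_volume_fraction, saxs_q_grid,
                noise_scale=saxs_noise_scale, seed=seed_saxs)
            saxs.append(prof)
    return ScanSimulation(frames=frames, truth=truth, saxs_profiles=saxs,
                          config=config)


# ---------------------------------------------------------------------------
# in situ indentation series
# ---------------------------------------------------------------------------

@dataclass
class IndentationSeries:
    """Per-force frame grids + ground truth + force-displacement table."""

    forces_mn: list
    frames_by_force: dict           # force -> list[DetectorFrame]
    truth: pd.DataFrame             # per (force, point) ground truth
    force_displacement: pd.DataFrame
    tip_position_um: tuple[float, float]
    config: Optional[SimulationConfig] = None


def indentation_grid_um(extent_um: float = 70.0,
                        spacing_um: float = 2.0) -> pd.DataFrame:
    """Indentation scan grid in um relative coordinates (floor/step + 1)."""
    n = int(math.floor(extent_um / spacing_um + 1e-9)) + 1
    xs = spacing_um * np.arange(n)
    gy, gx = np.meshgrid(xs, xs, indexing="ij")
    return pd.DataFrame({"x_um": gx.ravel(), "y_um": gy.ravel()})


def strain_ratio_field(field: GroundTruthField, force_mn: float,
                       distance_um) -> np.ndarray:
    """Ground-truth ellipse ratio vs distance from the tip (exponential kernel)."""
    tip = field.tip_strain_ratio(force_mn)
    r = np.asarray(distance_um, dtype=float)
    return 1.0 - (1.0 - tip) * np.exp(-r / field.strain_decay_um)


def simulate_indentation_series(field: GroundTruthField,
                                forces_mn: Sequence[float],
                                config: SimulationConfig,
                                extent_um: float = 70.0,
                                spacing_um: float = 2.0,
                                tip_position_um: Optional[tuple[float, float]] = None,
                                displacement_prefactor_um: float = 0.05,
                                displacement_exponent: float = 2.0 / 3.0,
                                ) -> IndentationSeries:
    """Simulate a fixed-force scan series under a nanoindenter.

    Per force, a grid of frames over ``extent_um`` x ``extent_um`` at
    ``spacing_um`` is generated; the ellipse axis ratio at each point decays
    from its tip value back to 1 with the field's exponential kernel. A
    synthetic force-displacement table follows the monotone power law
    ``x = c * F**p`` (Hertz-like default p = 2/3).
    """
    forces = [float(f) for f in forces_mn]
    if any(f < 0 or f > 2500 for f in forces):
        raise ValueError("forces must lie within [0, 2500] mN")
    if any(b < a for a, b in zip(forces, forces[1:])):
        raise ValueError("forces must be non-decreasing")
    pos = indentation_grid_um(extent_um, spacing_um)
    if tip_position_um is None:
        tip_position_um = (extent_um / 2.0, extent_um / 2.0)
    tx, ty = tip_position_um
    if not (0.0 <= tx <= extent_um and 0.0 <= ty <= extent_um):
        raise ValueError(
            f"tip position {tip_position_um} um lies outside the "
            f"{extent_um} um scan grid")
    dist = np.hypot(pos["x_um"] - tx, pos["y_um"] - ty).to_numpy()
    children = np.random.SeedSequence(config.seed).spawn(len(forces) * len(pos))
    frames_by_force: dict[float, list] = {}
    rows = []
    idx = 0
    for f in forces:
        ratios = strain_ratio_field(field, f, dist)
        frames = []
        for (x, y), ratio, r_tip in zip(pos.itertuples(index=False), ratios, dist):
            seed = int(children[idx].generate_state(1)[0] % (2 ** 31))
            idx += 1
            frames.append(simulate_xrd_frame(
                config, d_nm=field.d_spacing_at_interface_nm,
                tau_nm=field.crystallite_size_nm, strain_ratio=float(ratio),
                seed=seed,
                metadata={"x_um": float(x), "y_um": float(y), "force_mn": f}))
            rows.append({"force_mn": f, "x_um": float(x), "y_um": float(y),
                         "tip_distance_um": float(r_tip),
                         "strain_ratio": float(ratio)})
        frames_by_force[f] = frames
    truth = pd.DataFrame(rows)
    fd = pd.DataFrame({
        "force_mn": forces,
        "displacement_um": [displacement_prefactor_um * f ** displacement_exponent
                            for f in forces],
    })
    return IndentationSeries(forces_mn=forces, frames_by_force=frames_by_force,
                             truth=truth, force_displacement=fd,
                             tip_position_um=(float(tx), float(ty)),
                             config=config)
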