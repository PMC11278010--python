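"""End-to-end workflows: simulate, scanning-map analysis, indentation analysis.

Each workflow is driven by a plain dict configuration (YAML on disk), runs
the library stages in order and writes CSV tables, float-TIFF maps, PNG
figures and a JSON run report into the configured output directory. Every
CSV carries the configuration hash in a comment header and the report lists
all outputs, so a saved config re-executes to byte-identical tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, plots
from .gradients import distance_transform, fit_gradient, gradient_summary, \
    profile_by_distance
from .geometry import ExperimentGeometry
from .reduction import calibrate_geometry
from .saxs import TParameterConfig, t_parameter_map
from .simulate import (GroundTruthField, ScanGrid, SimulationConfig,
                       simulate_indentation_series, simulate_lab6_frame,
                       simulate_scan_grid)
from .strain import strain_map_series, strain_vs_tip_distance
from .xrd import UltrastructureConfig, map_ultrastructure


class PipelineError(RuntimeError):
    """A stage-attributed workflow failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _require_path(cfg: dict, key: str, stage: str) -> Path:
    if key not in cfg:
        raise PipelineError(stage, f"config lacks required path {key!r}")
    p = Path(cfg[key])
    if not p.exists():
        raise PipelineError(stage, f"input path does not exist: {p}")
    return p


def _geometry_from_config(cfg: dict) -> ExperimentGeometry:
    g = cfg["geometry"]
    return ExperimentGeometry(wavelength=g["wavelength_nm"],
                              beam_center=(g["beam_center_row"],
                                           g["beam_center_col"]),
                              distance_mm=g["distance_mm"],
                              pixel_size_um=g["pixel_size_um"])


def _sim_config(cfg: dict) -> SimulationConfig:
    return SimulationConfig(**cfg.get("simulation", {}))


def _field(cfg: dict) -> GroundTruthField:
    return GroundTruthField(**cfg.get("field", {}))


# ---------------------------------------------------------------------------
# simulation workflows
# ---------------------------------------------------------------------------

def run_simulate_scan(cfg: dict) -> dict:
    """Simulate a scan grid and write the HDF5 archive + truth sidecar."""
    out = Path(cfg.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = _sim_config(cfg)
    grid = ScanGrid(**cfg.get("grid", {}))
    field = _field(cfg)
    saxs_q = None
    if cfg.get("saxs", {}).get("enabled", True):
        s = cfg.get("saxs", {})
        saxs_q = np.linspace(s.get("q_min", 0.01), s.get("q_max", 4.0),
                             int(s.get("n_q", 800)))
    sim = simulate_scan_grid(field, grid, sim_cfg, saxs_q_grid=saxs_q,
                             saxs_noise_scale=cfg.get("saxs", {}).get(
                                 "noise_scale", 0.0))
    h5_path = out / cfg.get("scan_file", "scan.h5")
    io.write_scan_h5(h5_path, sim.frames, saxs_profiles=sim.saxs_profiles,
                     attrs={"energy_kev": sim_cfg.energy_kev,
                            "seed": sim_cfg.seed})
    chash = io.config_hash(cfg)
    io.write_table_csv(out / "ground_truth.csv", sim.truth, chash)
    if cfg.get("calibrant", True):
        lab6, spacings = simulate_lab6_frame(sim_cfg, seed=sim_cfg.seed + 1)
        io.write_frame_tiff(out / "lab6.tiff", lab6)
        io.write_table_csv(out / "lab6_spacings.csv",
                           pd.DataFrame({"d_nm": spacings}), chash)
    io.save_geometry(sim_cfg.geometry(), out / "true_geometry.txt")
    return {"scan_file": str(h5_path), "n_frames": len(sim.frames),
            "config_hash": chash}


def run_simulate_indentation(cfg: dict) -> dict:
    """Simulate an indentation force series and write one HDF5 per force."""
    out = Path(cfg.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = _sim_config(cfg)
    field = _field(cfg)
    forces = [float(f) for f in cfg.get("forces_mn", [0.0, 150.0, 250.0])]
    ind = cfg.get("indentation", {})
    series = simulate_indentation_series(
        field, forces, sim_cfg,
        extent_um=ind.get("extent_um", 70.0),
        spacing_um=ind.get("spacing_um", 2.0),
        tip_position_um=tuple(ind["tip_position_um"])
        if "tip_position_um" in ind else None)
    frames = [f for force in forces for f in series.frames_by_force[force]]
    per_frame_force = [force for force in forces
                       for _ in series.frames_by_force[force]]
    h5_path = out / cfg.get("scan_file", "indent.h5")
    io.write_scan_h5(h5_path, frames, forces_mn=per_frame_force,
                     tip_position_um=series.tip_position_um,
                     position_key="um",
                     attrs={"energy_kev": sim_cfg.energy_kev,
                            "seed": sim_cfg.seed})
    chash = io.config_hash(cfg)
    io.write_table_csv(out / "ground_truth.csv", series.truth, chash)
    fd = series.force_displacement.copy()
    fd.insert(0, "time_s", np.arange(len(fd), dtype=float))
    io.write_table_csv(out / "force_displacement.csv", fd, chash)
    io.save_geometry(sim_cfg.geometry(), out / "true_geometry.txt")
    return {"scan_file": str(h5_path), "n_frames": len(frames),
            "config_hash": chash}


# ---------------------------------------------------------------------------
# analysis workflows
# ---------------------------------------------------------------------------

def _resolve_geometry(cfg: dict, out: Path) -> ExperimentGeometry:
    """Geometry from calibration (preferred), a geometry file, or config."""
    if "calibrant_file" in cfg:
        cal_path = _require_path(cfg, "calibrant_file", "calibration")
        spacings_path = _require_path(cfg, "calibrant_spacings", "calibration")
        frame = io.read_frame_tiff(cal_path)
        d_ref = io.read_table_csv(spacings_path)["d_nm"].to_numpy()
        initial = _geometry_from_config(cfg)
        geom = calibrate_geometry([frame], d_ref, initial)
        io.save_geometry(geom, out / "calibrated_geometry.txt")
        return geom
    if "geometry_file" in cfg:
        return io.load_geometry(_require_path(cfg, "geometry_file", "geometry"))
    if "geometry" in cfg:
        return _geometry_from_config(cfg)
    raise PipelineError("geometry", "no geometry source in config "
                                    "(calibrant_file / geometry_file / geometry)")


def _interface_distances(cfg: dict, records: pd.DataFrame) -> pd.DataFrame:
    """Attach distance-from-interface (mm) to the record table."""
    iface = cfg.get("interface", {"type": "half_plane", "x_mm": 0.0})
    rec = records.copy()
    if iface.get("type", "half_plane") == "half_plane":
        rec["distance_mm"] = rec["x_mm"] - float(iface.get("x_mm", 0.0))
    elif iface["type"] == "mask":
        mask = np.loadtxt(iface["path"], delimiter=",").astype(bool)
        step_mm = float(iface["step_mm"])
        dist = distance_transform(mask, step_mm * 1000.0)
        nx = rec["x_mm"].nunique()
        ny = rec["y_mm"].nunique()
        if mask.shape != (ny, nx):
            raise PipelineError("distance", f"interface mask shape {mask.shape} "
                                            f"does not match scan grid ({ny}, {nx})")
        rec = rec.sort_values(["y_mm", "x_mm"]).reset_index(drop=True)
        rec["distance_mm"] = dist.ravel()
    else:
        raise PipelineError("distance", f"unknown interface type {iface['type']!r}")
    return rec


def run_scan_pipeline(cfg: dict) -> dict:
    """Scanning-map analysis: reduction -> XRD -> SAXS -> spatial gradients.

    Returns a run report dict (also written as JSON) with config hash, QC
    counts and the list of written outputs.
    """
    out = Path(cfg.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(cfg)
    scan_path = _require_path(cfg, "scan_file", "input")
    data = io.read_scan_h5(scan_path)
    geom = _resolve_geometry(cfg, out)

    xrd_cfg = UltrastructureConfig(**cfg.get("xrd", {}))
    records = map_ultrastructure(data["frames"], geom, xrd_cfg)
    if data["saxs_profiles"] is not None:
        profiles = {(float(p[0]), float(p[1])): prof
                    for p, prof in zip(data["positions"],
                                       data["saxs_profiles"])}
        records = t_parameter_map(profiles, records,
                                  TParameterConfig(**cfg.get("saxs_fit", {})))
    records = _interface_distances(cfg, records)
    io.write_table_csv(out / "records.csv", records, chash)

    written = ["records.csv"]
    params = {"d_spacing": ("d_spacing_nm", "qc_pass"),
              "crystallite_size": ("crystallite_nm", "qc_pass")}
    if "t_parameter_nm" in records.columns:
        params["t_parameter"] = ("t_parameter_nm", "t_qc_pass")
    bin_width = float(cfg.get("profile_bin_width_mm", 0.054))
    max_dist = float(cfg.get("gradient_max_distance_mm", 0.8))
    profiles_out = {}
    for name, (col, qc) in params.items():
        io.write_parameter_map_tiff(out / f"map_{name}.tiff", records, col,
                                    description=f"config_hash={chash}")
        written.append(f"map_{name}.tiff")
        try:
            prof = profile_by_distance(records, col, bin_width, qc_col=qc)
            io.write_table_csv(out / f"profile_{name}.csv", prof, chash)
            plots.plot_distance_profile(prof, name, out / f"profile_{name}.png")
            written += [f"profile_{name}.csv", f"profile_{name}.png"]
            profiles_out[name] = prof
        except ValueError:
            pass
    summary = gradient_summary(
        records, {n: c for n, (c, _) in params.items()},
        max_distance_mm=max_dist,
        qc_cols={n: qc for n, (_, qc) in params.items()})
    io.write_table_csv(out / "gradients.csv", summary, chash)
    plots.plot_gradient_bars(summary, out / "gradients.png")
    written += ["gradients.csv", "gradients.png"]

    report = {
        "workflow": "scan",
        "periscat_version": __version__,
        "config_hash": chash,
        "n_frames": len(data["frames"]),
        "n_qc_pass_xrd": int(records["qc_pass"].sum()),
        "n_qc_pass_saxs": int(records["t_qc_pass"].sum())
        if "t_qc_pass" in records.columns else None,
        "geometry": {"wavelength_nm": geom.wavelength,
                     "beam_center": list(geom.beam_center),
                     "distance_mm": geom.distance_mm},
        "outputs": written,
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2))
    report["records"] = records
    report["gradients"] = summary
    report["profiles"] = profiles_out
    return report


def run_indentation_pipeline(cfg: dict) -> dict:
    """Indentation analysis: per-force strain maps + tip-distance profiles."""
    out = Path(cfg.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(cfg)
    scan_path = _require_path(cfg, "scan_file", "input")
    data = io.read_scan_h5(scan_path)
    geom = _resolve_geometry(cfg, out)
    if data["forces"] is None:
        raise PipelineError("input", "indentation archive lacks /forces")
    tip = data["tip_position_um"]
    if tip is None:
        tip = tuple(cfg.get("tip_position_um", (None, None)))
    if tip[0] is None:
        raise PipelineError("input", "tip position missing from archive and config")

    frames_by_force: dict[float, list] = {}
    for frame, force in zip(data["frames"], data["forces"]):
        frames_by_force.setdefault(float(force), []).append(frame)
    st_cfg = cfg.get("strain", {})
    strain_df = strain_map_series(frames_by_force, geom,
                                  n_sectors=int(st_cfg.get("n_sectors", 36)),
                                  window=tuple(st_cfg["window"])
                                  if "window" in st_cfg else None)
    io.write_table_csv(out / "strain_records.csv", strain_df, chash)
    written = ["strain_records.csv"]
    profiles = {}
    for force in sorted(frames_by_force):
        sub = strain_df[strain_df["force_mn"] == force]
        io.write_parameter_map_tiff(out / f"strain_map_{force:g}mN.tiff",
                                    sub, "epsilon", x_col="x_um", y_col="y_um",
                                    description=f"config_hash={chash}")
        plots.plot_strain_map(sub, out / f"strain_map_{force:g}mN.png")
        written += [f"strain_map_{force:g}mN.tiff", f"strain_map_{force:g}mN.png"]
        if sub["epsilon"].notna().any():
            prof = strain_vs_tip_distance(
                sub, tip, bin_width_um=float(st_cfg.get("bin_width_um", 5.0)))
            io.write_table_csv(out / f"strain_profile_{force:g}mN.csv", prof,
                               chash)
            plots.plot_strain_profile(prof, out / f"strain_profile_{force:g}mN.png")
            written += [f"strain_profile_{force:g}mN.csv",
                        f"strain_profile_{force:g}mN.png"]
            profiles[force] = prof
    fd = None
    if "force_displacement_file" in cfg:
        from .strain import load_force_displacement
        fd, fd_report = load_force_displacement(
            _require_path(cfg, "force_displacement_file", "input"))
        io.write_table_csv(out / "force_displacement_clean.csv", fd, chash)
        plots.plot_force_displacement(fd, out / "force_displacement.png")
        written += ["force_displacement_clean.csv", "force_displacement.png"]

    report = {
        "workflow": "indentation",
        "periscat_version": __version__,
        "config_hash": chash,
        "n_frames": len(data["frames"]),
        "forces_mn": sorted(frames_by_force),
        "n_converged": int(strain_df["converged"].sum()),
        "outputs": written,
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2))
    report["strain_records"] = strain_df
    report["profiles"] = profiles
    report["force_displacement"] = fd
    return report
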