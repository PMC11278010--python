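"""File formats: HDF5 scan/indentation archives, TIFF frames and maps,
plain-text geometry files, CSV tables with config-hash headers.

HDF5 layout (one file per scan):
  /frames            (n, rows, cols) float32 detector counts
  /mask              (rows, cols) uint8, 1 = excluded pixel
  /motor_positions   (n, 2) float64, (x, y) in mm (scan) or um (indentation)
  /forces            (n,) float64 mN, indentation files only
  /tip_position      (2,) float64 um, indentation files only
  /saxs/q, /saxs/intensity, /saxs/sigma   optional per-point 1D profiles
Scalar acquisition metadata lives in root attributes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .frames import DetectorFrame
from .geometry import ExperimentGeometry
from .reduction import RadialProfile


def config_hash(config: dict) -> str:
    """Stable short hash of a (JSON-serializable) configuration mapping.

    The output directory is excluded so that re-running a saved config into
    a different location yields the same hash (and byte-identical tables).
    """
    payload = {k: v for k, v in config.items() if k != "output_dir"}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# geometry files: documented plain-text key/value format
# ---------------------------------------------------------------------------

def save_geometry(geometry: ExperimentGeometry, path) -> None:
    """Write a geometry as `key = value` lines (bit-stable across runs)."""
    lines = [
        f"wavelength_nm = {geometry.wavelength!r}",
        f"beam_center_row = {geometry.beam_center[0]!r}",
        f"beam_center_col = {geometry.beam_center[1]!r}",
        f"distance_mm = {geometry.distance_mm!r}",
        f"pixel_size_um = {geometry.pixel_size_um!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_geometry(path) -> ExperimentGeometry:
    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = float(value)
    return ExperimentGeometry(
        wavelength=kv["wavelength_nm"],
        beam_center=(kv["beam_center_row"], kv["beam_center_col"]),
        distance_mm=kv["distance_mm"],
        pixel_size_um=kv["pixel_size_um"])


# ---------------------------------------------------------------------------
# HDF5 scan archives
# ---------------------------------------------------------------------------

def write_scan_h5(path, frames: Sequence[DetectorFrame],
                  attrs: Optional[dict] = None,
                  saxs_profiles: Optional[Sequence[RadialProfile]] = None,
                  forces_mn=None, tip_position_um=None,
                  position_key: str = "mm") -> None:
    """Write a frame collection (and optional SAXS profiles) to HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([f.counts for f in frames]).astype(np.float32)
    mask = frames[0].mask
    if position_key == "mm":
        pos = np.array([[f.metadata.get("x_mm", np.nan),
                         f.metadata.get("y_mm", np.nan)] for f in frames])
    else:
        pos = np.array([[f.metadata.get("x_um", np.nan),
                         f.metadata.get("y_um", np.nan)] for f in frames])
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=stack, compression="gzip", shuffle=True)
        h5.create_dataset("mask", data=mask.astype(np.uint8))
        h5.create_dataset("motor_positions", data=pos)
        h5.attrs["position_units"] = position_key
        if forces_mn is not None:
            h5.create_dataset("forces", data=np.asarray(forces_mn, dtype=float))
        if tip_position_um is not None:
            h5.create_dataset("tip_position",
                              data=np.asarray(tip_position_um, dtype=float))
        if saxs_profiles is not None:
            g = h5.create_group("saxs")
            g.create_dataset("q", data=saxs_profiles[0].q)
            g.create_dataset("intensity",
                             data=np.stack([p.intensity for p in saxs_profiles]))
            g.create_dataset("sigma",
                             data=np.stack([p.sigma for p in saxs_profiles]))
        for k, v in (attrs or {}).items():
            h5.attrs[k] = v


def read_scan_h5(path) -> dict:
    """Read a scan archive back into frames + optional profiles/forces."""
    with h5py.File(path, "r") as h5:
        stack = h5["frames"][()]
        mask = h5["mask"][()].astype(bool)
        pos = h5["motor_positions"][()]
        units = h5.attrs.get("position_units", "mm")
        key_x, key_y = (f"x_{units}", f"y_{units}")
        forces = h5["forces"][()] if "forces" in h5 else None
        tip = tuple(h5["tip_position"][()]) if "tip_position" in h5 else None
        saxs = None
        if "saxs" in h5:
            q = h5["saxs/q"][()]
            inten = h5["saxs/intensity"][()]
            sig = h5["saxs/sigma"][()]
            saxs = [RadialProfile(q=q, intensity=inten[i], sigma=sig[i])
                    for i in range(inten.shape[0])]
        attrs = dict(h5.attrs)
    frames = []
    for i in range(stack.shape[0]):
        meta = {key_x: float(pos[i, 0]), key_y: float(pos[i, 1])}
        if forces is not None:
            meta["force_mn"] = float(forces[i])
        frames.append(DetectorFrame(counts=stack[i].astype(np.float64),
                                    mask=mask, metadata=meta))
    return {"frames": frames, "mask": mask, "positions": pos,
            "forces": forces, "tip_position_um": tip,
            "saxs_profiles": saxs, "attrs": attrs}


# ---------------------------------------------------------------------------
# TIFF and CSV outputs
# ---------------------------------------------------------------------------

def write_frame_tiff(path, frame: DetectorFrame) -> None:
    """One frame as 32-bit float TIFF."""
    tifffile.imwrite(path, frame.counts.astype(np.float32))


def read_frame_tiff(path, mask: Optional[np.ndarray] = None) -> DetectorFrame:
    counts = tifffile.imread(path).astype(np.float64)
    return DetectorFrame(counts=counts, mask=mask)


def write_parameter_map_tiff(path, records: pd.DataFrame, value_col: str,
                             x_col: str = "x_mm", y_col: str = "y_mm",
                             description: str = "") -> np.ndarray:
    """Pivot a record table to a float TIFF map (NaN for QC-failed points)."""
    grid = records.pivot_table(index=y_col, columns=x_col, values=value_col,
                               dropna=False, aggfunc="mean", sort=True)
    img = grid.to_numpy(dtype=np.float32)
    tifffile.imwrite(path, img, description=description)
    return img


def write_table_csv(path, table: pd.DataFrame, cfg_hash: str = "") -> None:
    """CSV with a comment header carrying the run's config hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if cfg_hash:
            fh.write(f"# config_hash={cfg_hash}\n")
        table.to_csv(fh, index=False, lineterminator="\n")


def read_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_profile_csv(path, profile: RadialProfile, cfg_hash: str = "") -> None:
    df = pd.DataFrame({"q": profile.q, "I": profile.intensity,
                       "sigma": profile.sigma, "n_pixels": profile.n_pixels})
    write_table_csv(path, df, cfg_hash)


def read_profile_csv(path) -> RadialProfile:
    df = read_table_csv(path)
    return RadialProfile(q=df["q"].to_numpy(), intensity=df["I"].to_numpy(),
                         sigma=df["sigma"].to_numpy(),
                         n_pixels=df["n_pixels"].to_numpy())


# ---------------------------------------------------------------------------
# run configuration (plain-text YAML)
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return cfg


def save_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
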