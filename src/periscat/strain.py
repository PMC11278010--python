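"""Relative lattice-strain mapping from elliptically distorted Debye rings.

Under an indenter, hydroxyapatite crystallites deform elastically and the
(002) Debye-Scherrer ring becomes an ellipse in reciprocal space. Because
bone is heterogeneous even at zero load, absolute peak-shift analysis
between force steps would require perfect registration of the scans; the
per-frame ellipse ratio

    epsilon_relative = a / b   (a: semi-minor, b: semi-major half axis)

needs no registration at all: each scan position delivers its own relative
strain at the force at which the scan was acquired. This module extracts
ring points sector-by-sector (Gaussian radial peak per azimuthal sector,
mapped to Cartesian q-space), fits a direct least-squares ellipse, and
propagates point-fit residuals into a 1-sigma uncertainty on epsilon via

    sigma_eps^2 = (sigma_a / b)^2 + (a sigma_b / b^2)^2.

Since a <= b by construction epsilon <= 1; strain profiles report the
deviation 1 - epsilon, which increases toward the tip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from ._fitting import fit_gaussian_peak
from .frames import DetectorFrame
from .geometry import ExperimentGeometry
from .reduction import azimuthal_integrate


def extract_ring_points(frame: DetectorFrame, geometry: ExperimentGeometry,
                        n_sectors: int = 36,
                        window: Optional[tuple[float, float]] = None,
                        correct_sector_smearing: bool = True,
                        ) -> tuple[np.ndarray, pd.DataFrame]:
    """Locate the diffraction ring sector-by-sector in reciprocal space.

    Per azimuthal sector the radial intensity (within the q ``window``) is
    fit with a Gaussian; the fitted peak position at the sector-center
    azimuth gives one Cartesian q-space point. Returns the (m, 2) point set
    and a per-sector detail table (azimuth, q peak, its 1-sigma error);
    failed sectors are omitted and counted in the table attribute.

    Pooling a sector averages the ring radius over the sector's azimuth
    span, which attenuates the second-harmonic (elliptical) modulation by
    ``sin(w)/w`` (w: sector width in rad). With
    ``correct_sector_smearing`` the extracted radii are deconvolved by
    rescaling their fitted second harmonic, which removes the resulting
    small bias toward circularity without touching the point noise.

    When ``window`` is None it is chosen automatically around the maximum
    of the full-circle profile.
    """
    if n_sectors < 8:
        raise ValueError("need at least 8 azimuthal sectors")
    if window is None:
        prof = azimuthal_integrate(frame, geometry, n_bins=512)
        v = prof.valid
        q_pk = prof.q[v][np.argmax(prof.intensity[v])]
        window = (0.9 * q_pk, 1.1 * q_pk)
    qmap = geometry.q_map(frame.shape)
    azmap = geometry.azimuth_map(frame.shape)
    in_window = (~frame.mask) & (qmap >= window[0]) & (qmap <= window[1])
    edges = np.linspace(0.0, 360.0, n_sectors + 1)
    pts, rows = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = in_window & (azmap >= lo) & (azmap < hi)
        if np.count_nonzero(sel) < 8:
            continue
        res = fit_gaussian_peak(qmap[sel], frame.counts[sel])
        if res is None:
            continue
        phi = math.radians(0.5 * (lo + hi))
        qc = res["center"]
        pts.append((phi, qc))
        rows.append({"azimuth_deg": 0.5 * (lo + hi), "q_peak": qc,
                     "q_sigma": res["center_err"]})
    if len(pts) < 6:
        raise ValueError(
            f"only {len(pts)} of {n_sectors} sectors yielded a ring point; "
            "ellipse is under-determined (need >= 6)")
    phi = np.array([p[0] for p in pts])
    r = np.array([p[1] for p in pts])
    if correct_sector_smearing:
        w = 2.0 * np.pi / n_sectors
        k2 = math.sin(w) / w
        H = np.column_stack([np.ones_like(phi), np.cos(2 * phi), np.sin(2 * phi)])
        coef, *_ = np.linalg.lstsq(H, r, rcond=None)
        r = r + (1.0 / k2 - 1.0) * (H[:, 1] * coef[1] + H[:, 2] * coef[2])
    points = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    return points, pd.DataFrame(rows)


@dataclass
class EllipseFit:
    """Direct least-squares ellipse fit of a ring point set in q-space."""

    semi_minor: float          # a, nm^-1
    semi_major: float          # b, nm^-1
    orientation: float         # rad, of the semi-major axis, in [0, pi)
    center: tuple[float, float]
    epsilon_relative: float    # a / b, in (0, 1]
    epsilon_sigma: float
    axis_sigma: float          # common 1-sigma on each semi-axis
    n_ring_points: int
    rms_residual: float
    converged: bool


def propagate_ratio_sigma(a: float, b: float, sigma_a: float,
                          sigma_b: float, cov_ab: float = 0.0) -> float:
    """First-order uncertainty of the ratio a/b from per-axis uncertainties.

    ``cov_ab`` extends the independent-axis formula to correlated axis
    estimates; for the sector-point ellipse fit the shared second-harmonic
    amplitude makes the axes anticorrelated (an amplitude error pushes a
    down exactly as it pushes b up), which widens the ratio uncertainty.
    """
    var = (sigma_a / b) ** 2 + (a * sigma_b / b ** 2) ** 2 \
        - 2.0 * a * cov_ab / b ** 3
    return math.sqrt(max(var, 0.0))


def _conic_to_ellipse(coef: np.ndarray):
    """Semi-axes, orientation and center of the conic ax²+bxy+cy²+dx+ey+f=0."""
    A, B, C, D, E, F = coef
    disc = B * B - 4.0 * A * C
    if disc >= 0:
        return None
    cx = (2.0 * C * D - B * E) / disc
    cy = (2.0 * A * E - B * D) / disc
    # evaluate at the center to normalize; fix the arbitrary overall sign
    Fc = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    if Fc > 0:
        A, B, C, Fc = -A, -B, -C, -Fc
    if Fc == 0:
        return None
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    evals, evecs = np.linalg.eigh(M / -Fc)
    if np.any(evals <= 0):
        return None
    axes = 1.0 / np.sqrt(evals)            # descending axis = smallest eval
    order = np.argsort(axes)               # a (minor) first
    a, b = axes[order[0]], axes[order[1]]
    major_vec = evecs[:, order[1]]
    orientation = math.atan2(major_vec[1], major_vec[0]) % math.pi
    return float(a), float(b), float(orientation), (float(cx), float(cy))


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Fit an ellipse to q-space ring points (direct least-squares conic).

    Uses the ellipse-specific constrained conic fit (the generalized
    eigenvalue formulation), numerically centered and scaled. Per-axis
    uncertainties come from the radial point residuals: for m points at
    roughly uniform azimuth on a near-circular ring, each semi-axis carries
    ``sigma_axis = rms_residual * sqrt(3 / m)`` (mean + second-harmonic
    amplitude estimation), and the epsilon uncertainty follows by
    first-order propagation. A degenerate (non-elliptical) point set yields
    ``converged=False`` rather than an exception.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise ValueError("need an (m >= 6, 2) point array")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("points are collinear; no ellipse is determined")
    mean = pts.mean(axis=0)
    scale = float(np.mean(np.linalg.norm(pts - mean, axis=1)))
    x, y = ((pts - mean) / scale).T

    failed = EllipseFit(np.nan, np.nan, np.nan, (np.nan, np.nan), np.nan,
                        np.nan, np.nan, pts.shape[0], np.nan, False)
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    C1 = np.array([[0.0, 0.0, 2.0], [0.0, -1.0, 0.0], [2.0, 0.0, 0.0]])
    try:
        T = -np.linalg.solve(S3, S2.T)
        M = np.linalg.solve(C1, S1 + S2 @ T)
        evals, evecs = np.linalg.eig(M)
    except np.linalg.LinAlgError:
        return failed
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    good = np.where(np.isreal(evals) & (cond > 0))[0]
    if good.size == 0:
        return failed
    a1 = np.real(evecs[:, good[0]])
    coef = np.concatenate([a1, T @ a1])
    ell = _conic_to_ellipse(coef)
    if ell is None:
        return failed
    a_s, b_s, orientation, (cx_s, cy_s) = ell
    a, b = a_s * scale, b_s * scale
    center = (cx_s * scale + mean[0], cy_s * scale + mean[1])

    # radial residuals about the fitted center
    dx = pts[:, 0] - center[0]
    dy = pts[:, 1] - center[1]
    phi = np.arctan2(dy, dx) - orientation
    r_model = a * b / np.sqrt((a * np.cos(phi)) ** 2 + (b * np.sin(phi)) ** 2)
    resid = np.hypot(dx, dy) - r_model
    m = pts.shape[0]
    rms = float(np.sqrt(np.mean(resid ** 2)))
    # unbiased point-noise estimate: the conic consumes 5 shape dof
    sigma_point = float(np.sqrt(np.sum(resid ** 2) / max(m - 5, 1)))
    # for m near-uniform azimuths the mean radius carries sigma^2/m and the
    # second-harmonic amplitude 2 sigma^2/m; each semi-axis combines both
    # (3 sigma^2/m) and the shared amplitude anticorrelates them
    # (cov = -sigma^2/m)
    sigma_axis = sigma_point * math.sqrt(3.0 / m)
    cov_ab = -sigma_point ** 2 / m
    eps = a / b
    return EllipseFit(semi_minor=a, semi_major=b, orientation=orientation,
                      center=center, epsilon_relative=eps,
                      epsilon_sigma=propagate_ratio_sigma(a, b, sigma_axis,
                                                          sigma_axis, cov_ab),
                      axis_sigma=sigma_axis, n_ring_points=m,
                      rms_residual=rms, converged=True)


# ---------------------------------------------------------------------------
# per-force strain maps and tip-distance profiles
# ---------------------------------------------------------------------------

def strain_map(frames: Sequence[DetectorFrame], geometry: ExperimentGeometry,
               n_sectors: int = 36,
               window: Optional[tuple[float, float]] = None) -> pd.DataFrame:
    """Ellipse ratio per frame of one fixed-force scan grid."""
    rows = []
    for i, frame in enumerate(frames):
        rec = {"index": i,
               "x_um": frame.metadata.get("x_um", np.nan),
               "y_um": frame.metadata.get("y_um", np.nan),
               "force_mn": frame.metadata.get("force_mn", np.nan)}
        try:
            pts, _ = extract_ring_points(frame, geometry, n_sectors, window)
            fit = fit_ellipse(pts)
            rec.update(epsilon=fit.epsilon_relative if fit.converged else np.nan,
                       epsilon_sigma=fit.epsilon_sigma,
                       n_ring_points=fit.n_ring_points,
                       converged=fit.converged)
        except ValueError as exc:
            rec.update(epsilon=np.nan, epsilon_sigma=np.nan, n_ring_points=0,
                       converged=False, flags=str(exc))
        rows.append(rec)
    return pd.DataFrame(rows)


def strain_map_series(frames_by_force: dict, geometry: ExperimentGeometry,
                      n_sectors: int = 36,
                      window: Optional[tuple[float, float]] = None,
                      ) -> pd.DataFrame:
    """Strain maps for a whole force series (one map per fixed force).

    ``frames_by_force`` maps applied force (mN) to that scan's frame list;
    a force key of NaN/None is rejected since every map must carry its
    force. No inter-force registration is performed: the ratio is relative
    within each frame by construction.
    """
    maps = []
    for force, frames in frames_by_force.items():
        if force is None or (isinstance(force, float) and math.isnan(force)):
            raise ValueError("every scan grid must carry its applied force")
        df = strain_map(frames, geometry, n_sectors, window)
        df["force_mn"] = float(force)
        maps.append(df)
    return pd.concat(maps, ignore_index=True)


def strain_vs_tip_distance(strain_df: pd.DataFrame,
                           tip_position_um: tuple[float, float],
                           bin_width_um: float = 5.0) -> pd.DataFrame:
    """Bin the strain deviation 1 - epsilon by Euclidean tip distance.

    The 95% half-width per bin combines between-point scatter and the
    per-point fit uncertainties:
    ``t_{0.975, n-1} * sqrt(s^2/n + mean(sigma_i^2)/n)``.
    Empty bins are dropped.
    """
    df = strain_df[np.isfinite(strain_df["epsilon"])].copy()
    if df.empty:
        raise ValueError("no converged strain points")
    dist = np.hypot(df["x_um"] - tip_position_um[0],
                    df["y_um"] - tip_position_um[1]).to_numpy()
    eps = df["epsilon"].to_numpy(dtype=float)
    sig = df["epsilon_sigma"].to_numpy(dtype=float)
    idx = np.floor(dist / bin_width_um).astype(int)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        n = int(np.count_nonzero(sel))
        mean_eps = float(np.mean(eps[sel]))
        scatter = float(np.var(eps[sel], ddof=1)) if n >= 2 else 0.0
        prop = float(np.mean(np.nan_to_num(sig[sel]) ** 2))
        se = math.sqrt((scatter + prop) / n)
        tq = stats.t.ppf(0.975, max(n - 1, 1))
        rows.append({"tip_distance_um": (b + 0.5) * bin_width_um,
                     "mean_epsilon": mean_eps,
                     "mean_deviation": 1.0 - mean_eps,
                     "ci95_half_width": tq * se, "n": n})
    return pd.DataFrame(rows).sort_values("tip_distance_um").reset_index(drop=True)


def fit_strain_decay(profile: pd.DataFrame) -> tuple[float, float]:
    """Fit ``deviation = A exp(-r / L)`` to a tip-distance profile.

    Returns (amplitude A at the tip, decay length L in um).
    """
    r = profile["tip_distance_um"].to_numpy(dtype=float)
    y = profile["mean_deviation"].to_numpy(dtype=float)
    A0 = max(float(y.max()), 1e-9)
    L0 = max(float(r.mean()), 1.0)
    popt, _ = curve_fit(lambda x, A, L: A * np.exp(-x / L), r, y,
                        p0=[A0, L0], maxfev=4000)
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# indenter force-displacement logs
# ---------------------------------------------------------------------------

def load_force_displacement(path) -> tuple[pd.DataFrame, dict]:
    """Read an indenter log CSV (time_s, force_mn, displacement_um).

    Non-numeric rows are skipped and duplicated time stamps deduplicated
    (first occurrence kept); both counts are reported. Time stamps must be
    monotone after cleaning.
    """
    raw = pd.read_csv(path, comment="#")
    raw.columns = [c.strip().lower() for c in raw.columns]
    needed = ["time_s", "force_mn", "displacement_um"]
    for c in needed:
        if c not in raw.columns:
            raise ValueError(f"force-displacement log lacks column {c!r}")
    num = raw[needed].apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    n_skipped = int(bad.sum())
    num = num[~bad]
    n_dup = int(num["time_s"].duplicated().sum())
    num = num[~num["time_s"].duplicated()].reset_index(drop=True)
    if np.any(np.diff(num["time_s"].to_numpy()) <= 0):
        raise ValueError("time stamps are not monotone increasing")
    return num, {"n_skipped_rows": n_skipped, "n_deduplicated": n_dup}


def secant_stiffness(fd: pd.DataFrame, force_lo_mn: float,
                     force_hi_mn: float) -> float:
    """Secant stiffness Delta F / Delta x (mN/um) over a force window."""
    f = fd["force_mn"].to_numpy(dtype=float)
    x = fd["displacement_um"].to_numpy(dtype=float)
    x_lo = float(np.interp(force_lo_mn, f, x))
    x_hi = float(np.interp(force_hi_mn, f, x))
    if x_hi == x_lo:
        raise ValueError("zero displacement change over the requested window")
    return (force_hi_mn - force_lo_mn) / (x_hi - x_lo)
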