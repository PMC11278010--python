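"""Frame reduction: masking, geometry calibration, azimuthal integration.

Masked 2D detector frames become calibrated 1D I(q) profiles (full circle or
azimuthal sectors). The integrator is a plain histogram average with exact
pixel bookkeeping: each unmasked pixel contributes to exactly one q bin, so
pixel-count-weighted sector means recompose the full-circle mean identically.

Geometry calibration follows the standard powder-calibrant route (LaB6 for
the wide-angle setup, silver behenate at small angles): ring points are
located sector-by-sector with Gaussian radial fits, each ring is fit with a
circle to estimate the beam center, and the sample-detector distance is the
least-squares match between measured ring radii and radii predicted from the
reference lattice spacings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._fitting import fit_gaussian_peak
from .frames import DetectorFrame
from .geometry import ExperimentGeometry, radius_from_q, two_theta_from_q


@dataclass
class RadialProfile:
    """Azimuthally integrated 1D scattering profile.

    Per-bin ``intensity`` is the mean of contributing unmasked pixel values;
    ``sigma`` is the standard error of that mean (0 where fewer than two
    pixels contribute but the bin is occupied); bins with ``n_pixels == 0``
    are flagged with NaN intensity, never zero-filled. ``azimuth_range`` is
    the integrated sector in degrees ((0, 360) for the full circle).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray = None  # type: ignore[assignment]
    n_pixels: np.ndarray = None  # type: ignore[assignment]
    azimuth_range: tuple[float, float] = (0.0, 360.0)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1D arrays of equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is None:
            self.sigma = np.zeros_like(self.intensity)
        else:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.n_pixels is None:
            self.n_pixels = np.ones(self.q.shape, dtype=int)
        else:
            self.n_pixels = np.asarray(self.n_pixels)

    @property
    def valid(self) -> np.ndarray:
        """Bins that received at least one pixel and a finite intensity."""
        return (self.n_pixels > 0) & np.isfinite(self.intensity)


def apply_mask(frame: DetectorFrame, extra_mask: np.ndarray) -> DetectorFrame:
    """Union an additional bad-pixel mask into a frame (counts unchanged)."""
    extra_mask = np.asarray(extra_mask, dtype=bool)
    if extra_mask.shape != frame.counts.shape:
        raise ValueError(
            f"extra mask shape {extra_mask.shape} does not match frame shape "
            f"{frame.counts.shape}")
    return DetectorFrame(counts=frame.counts,
                         mask=frame.mask | extra_mask,
                         metadata=dict(frame.metadata))


def _sector_membership(azimuth_deg: np.ndarray,
                       sector: tuple[float, float]) -> np.ndarray:
    """Boolean membership of pixels in an azimuth interval, wrap-aware."""
    lo, hi = sector[0] % 360.0, sector[1] % 360.0
    if lo < hi:
        return (azimuth_deg >= lo) & (azimuth_deg < hi)
    # interval wraps through 0 degrees (e.g. (350, 10))
    return (azimuth_deg >= lo) | (azimuth_deg < hi)


def azimuthal_integrate(frame: DetectorFrame,
                        geometry: ExperimentGeometry,
                        n_bins: int = 2048,
                        q_range: Optional[tuple[float, float]] = None,
                        sector: Optional[tuple[float, float]] = None,
                        ) -> RadialProfile:
    """Azimuthally average a frame onto an equal-width q grid.

    Parameters
    ----------
    sector :
        Azimuth interval in degrees (counter-clockwise from +col axis) or
        ``None`` for the full circle. Intervals wrapping through 0 are
        allowed, e.g. ``(350, 10)``.
    q_range :
        (q_min, q_max) in nm^-1; defaults to the full q span of the unmasked
        pixels.
    """
    qmap = geometry.q_map(frame.shape)
    use = ~frame.mask
    if sector is not None:
        use = use & _sector_membership(geometry.azimuth_map(frame.shape), sector)
        if not np.any(use):
            raise ValueError(f"azimuth sector {sector} contains no unmasked pixels")
    qv = qmap[use]
    if qv.size == 0:
        raise ValueError("no unmasked pixels to integrate")
    cv = frame.counts[use].astype(float)
    if q_range is None:
        q_lo, q_hi = float(qv.min()), float(qv.max())
    else:
        q_lo, q_hi = map(float, q_range)
        keep = (qv >= q_lo) & (qv <= q_hi)
        qv, cv = qv[keep], cv[keep]
    width = (q_hi - q_lo) / n_bins
    idx = np.minimum(((qv - q_lo) / width).astype(int), n_bins - 1)
    n = np.bincount(idx, minlength=n_bins)
    s1 = np.bincount(idx, weights=cv, minlength=n_bins)
    s2 = np.bincount(idx, weights=cv * cv, minlength=n_bins)
    sq = np.bincount(idx, weights=qv, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s1 / np.maximum(n, 1), np.nan)
        var = np.where(n > 1, (s2 - n * mean ** 2) / np.maximum(n - 1, 1), 0.0)
        sem = np.where(n > 1, np.sqrt(np.maximum(var, 0.0) / np.maximum(n, 1)), 0.0)
    sem = np.where(n > 0, sem, np.nan)
    # abscissa: mean pixel q of each occupied bin (bin center when empty);
    # removes the sampling bias of sparse in-bin q distributions on small
    # detectors while keeping q strictly increasing
    centers = q_lo + (np.arange(n_bins) + 0.5) * width
    q_out = np.where(n > 0, sq / np.maximum(n, 1), centers)
    return RadialProfile(q=q_out, intensity=mean, sigma=sem, n_pixels=n,
                         azimuth_range=sector if sector is not None else (0.0, 360.0))


# ---------------------------------------------------------------------------
# geometry calibration from powder-calibrant rings
# ---------------------------------------------------------------------------

def _fit_circle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) circle fit; returns (center_x, center_y, radius)."""
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    return float(cx), float(cy), float(np.sqrt(c + cx * cx + cy * cy))


def _ring_sector_points(frame: DetectorFrame, center: tuple[float, float],
                        r_pred_px: float, halfwidth_px: float,
                        n_sectors: int) -> np.ndarray:
    """Locate one calibrant ring sector-by-sector in pixel space.

    Returns an (m, 2) array of (col, row) ring points; sectors whose radial
    Gaussian fit fails are dropped.
    """
    rows = np.arange(frame.shape[0], dtype=float)[:, None]
    cols = np.arange(frame.shape[1], dtype=float)[None, :]
    dy = rows - center[0]
    dx = cols - center[1]
    r = np.hypot(dx, dy)
    az = np.degrees(np.arctan2(np.broadcast_to(dy, r.shape),
                               np.broadcast_to(dx, r.shape))) % 360.0
    annulus = (np.abs(r - r_pred_px) <= halfwidth_px) & ~frame.mask
    pts = []
    edges = np.linspace(0.0, 360.0, n_sectors + 1)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = annulus & (az >= lo) & (az < hi)
        if np.count_nonzero(sel) < 8:
            continue
        res = fit_gaussian_peak(r[sel], frame.counts[sel])
        if res is None:
            continue
        phi = np.radians(0.5 * (lo + hi))
        rc = res["center"]
        pts.append((center[1] + rc * np.cos(phi), center[0] + rc * np.sin(phi)))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def calibrate_geometry(calibrant_frames: Sequence[DetectorFrame],
                       reference_spacings: Sequence[float],
                       initial: ExperimentGeometry,
                       n_sectors: int = 36,
                       annulus_halfwidth_px: float = 25.0,
                       max_iter: int = 10,
                       tol: float = 1e-5) -> ExperimentGeometry:
    """Refine beam center and sample-detector distance from calibrant rings.

    Each reference lattice spacing predicts a ring radius through Bragg's
    law; measured sector-wise ring points give, per ring, a fitted circle
    (center + radius). The beam center is the point-weighted mean of the
    ring centers and the distance minimizes the squared radius residuals.
    Iterates until the center moves by less than ``tol`` pixels and the
    distance changes by less than a relative ``tol``.

    Returns a new :class:`ExperimentGeometry` with a ``calibration`` report
    (per-ring measured radii, residuals in px, iteration history) attached.

    Raises
    ------
    ValueError
        If fewer than two calibrant rings can be located, or the iteration
        does not converge (the residual history is included in the message).
    """
    d_ref = np.sort(np.asarray(reference_spacings, dtype=float))[::-1]
    if d_ref.size < 2:
        raise ValueError("calibration needs at least 2 reference ring spacings")
    wl = initial.wavelength
    center = [float(initial.beam_center[0]), float(initial.beam_center[1])]
    distance = float(initial.distance_mm)
    px_mm = initial.pixel_size_um / 1000.0
    history: list[dict] = []

    frame = calibrant_frames[0] if len(calibrant_frames) else None
    if frame is None:
        raise ValueError("no calibrant frames supplied")

    tan2t = np.tan(two_theta_from_q(2.0 * np.pi / d_ref, wl))
    for it in range(max_iter):
        ring_fits = []
        for t in tan2t:
            r_pred = distance * t / px_mm
            pts = _ring_sector_points(frame, tuple(center), r_pred,
                                      annulus_halfwidth_px, n_sectors)
            if pts.shape[0] < 6:
                continue
            cx, cy, radius = _fit_circle(pts[:, 0], pts[:, 1])
            ring_fits.append({"n_points": pts.shape[0], "center": (cy, cx),
                              "radius_px": radius, "tan_two_theta": float(t)})
        if len(ring_fits) < 2:
            raise ValueError(
                f"fewer than 2 calibrant rings detected (found {len(ring_fits)}); "
                "need >= 2 resolvable rings for distance refinement")
        weights = np.array([f["n_points"] for f in ring_fits], dtype=float)
        new_row = np.average([f["center"][0] for f in ring_fits], weights=weights)
        new_col = np.average([f["center"][1] for f in ring_fits], weights=weights)
        radii = np.array([f["radius_px"] for f in ring_fits]) * px_mm
        t_used = np.array([f["tan_two_theta"] for f in ring_fits])
        new_distance = float(np.sum(radii * t_used) / np.sum(t_used ** 2))
        residuals_px = (radii - new_distance * t_used) / px_mm
        shift = np.hypot(new_row - center[0], new_col - center[1])
        rel_d = abs(new_distance - distance) / distance
        center = [float(new_row), float(new_col)]
        distance = new_distance
        history.append({"iteration": it, "center": tuple(center),
                        "distance_mm": distance,
                        "rms_residual_px": float(np.sqrt(np.mean(residuals_px ** 2))),
                        "center_shift_px": float(shift),
                        "rel_distance_change": float(rel_d)})
        if shift < tol and rel_d < tol:
            break
    else:
        raise ValueError(
            "geometry calibration did not converge; residual history: "
            f"{history}")

    report = {
        "reference_spacings_nm": d_ref.tolist(),
        "measured_radii_px": (radii / px_mm).tolist(),
        "residuals_px": residuals_px.tolist(),
        "rms_residual_px": history[-1]["rms_residual_px"],
        "iterations": history,
    }
    return ExperimentGeometry(wavelength=wl, beam_center=tuple(center),
                              distance_mm=distance,
                              pixel_size_um=initial.pixel_size_um,
                              calibration=report)
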