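"""Detector geometry and reciprocal-space conversions.

All conversions between pixel radius, scattering angle and momentum transfer
are exact (no small-angle approximation): the hydroxyapatite (002) ring at
15 keV sits at 2-theta ~ 0.24 rad, where sin(theta) and tan(2*theta) differ
from their arguments at the percent level.

Conventions
-----------
* ``q = 4 pi sin(theta) / lambda`` in nm^-1, with ``2 theta = atan(r / D)``
  for a flat detector normal to the beam (r: in-plane radius from the beam
  center, D: sample-detector distance).
* ``lambda [nm] = 1.239842 / E [keV]`` (hc in keV nm).
* Pixel coordinates are (row, col); the azimuth is measured in degrees,
  counter-clockwise from the +col axis, in [0, 360).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: hc in keV * nm; lambda = HC_KEV_NM / E
HC_KEV_NM = 1.239842


def wavelength_nm(energy_kev: float) -> float:
    """Photon wavelength in nm for an energy in keV."""
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    return HC_KEV_NM / energy_kev


def q_from_two_theta(two_theta, wavelength: float):
    """Momentum transfer (nm^-1) from scattering angle 2-theta (rad)."""
    return 4.0 * np.pi / wavelength * np.sin(np.asarray(two_theta) / 2.0)


def two_theta_from_q(q, wavelength: float):
    """Scattering angle 2-theta (rad) from momentum transfer q (nm^-1)."""
    s = np.asarray(q) * wavelength / (4.0 * np.pi)
    if np.any(s > 1.0):
        raise ValueError("q not representable at this wavelength (sin theta > 1)")
    return 2.0 * np.arcsin(s)


def radius_from_q(q, wavelength: float, distance_mm: float):
    """In-plane detector radius (mm) at which momentum transfer q lands."""
    return distance_mm * np.tan(two_theta_from_q(q, wavelength))


def q_from_radius(r_mm, wavelength: float, distance_mm: float):
    """Momentum transfer (nm^-1) at in-plane detector radius r (mm)."""
    return q_from_two_theta(np.arctan2(np.asarray(r_mm), distance_mm), wavelength)


def bragg_d_from_q(q, order: int = 1):
    """Lattice spacing d (nm) from a Bragg peak position q (nm^-1).

    Bragg's law n*lambda = 2 d sin(theta) combined with the definition of q
    gives d = 2 pi n / q, independent of wavelength.
    """
    return 2.0 * np.pi * order / np.asarray(q)


@dataclass
class ExperimentGeometry:
    """Calibrated scattering geometry of one detector.

    Parameters
    ----------
    wavelength :
        Photon wavelength, nm.
    beam_center :
        Beam center in fractional pixels, (row, col).
    distance_mm :
        Sample-detector distance, mm.
    pixel_size_um :
        Pixel pitch, micrometres (square pixels).
    calibration :
        Optional residual report attached by :func:`periscat.reduction.
        calibrate_geometry`.
    """

    wavelength: float
    beam_center: tuple[float, float]
    distance_mm: float
    pixel_size_um: float
    calibration: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.wavelength <= 0 or self.distance_mm <= 0 or self.pixel_size_um <= 0:
            raise ValueError("wavelength, distance and pixel size must be positive")
        self.beam_center = tuple(float(c) for c in self.beam_center)

    # -- per-pixel maps ---------------------------------------------------

    def q_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel momentum transfer magnitude (nm^-1)."""
        return _pixel_maps(shape, self.beam_center[0], self.beam_center[1],
                           self.pixel_size_um, self.distance_mm,
                           self.wavelength)[0]

    def azimuth_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel azimuth in degrees, [0, 360)."""
        return _pixel_maps(shape, self.beam_center[0], self.beam_center[1],
                           self.pixel_size_um, self.distance_mm,
                           self.wavelength)[1]

    def radius_map_px(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel in-plane radius from the beam center, in pixels."""
        return _pixel_maps(shape, self.beam_center[0], self.beam_center[1],
                           self.pixel_size_um, self.distance_mm,
                           self.wavelength)[2]

    def q_at_nearest_edge(self, shape: tuple[int, int]) -> float:
        """Largest q whose full Debye-Scherrer ring fits on the detector."""
        cr, cc = self.beam_center
        r_px = min(cr, shape[0] - 1 - cr, cc, shape[1] - 1 - cc)
        return float(q_from_radius(r_px * self.pixel_size_um / 1000.0,
                                   self.wavelength, self.distance_mm))

    def replace(self, **kw) -> "ExperimentGeometry":
        return replace(self, **kw)


@functools.lru_cache(maxsize=16)
def _pixel_maps(shape, center_row, center_col, pixel_size_um, distance_mm,
                wavelength):
    """Cached (q, azimuth, radius_px) maps for one geometry + detector shape."""
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    dy = (rows - center_row)
    dx = (cols - center_col)
    r_px = np.hypot(dx, dy)
    r_mm = r_px * pixel_size_um / 1000.0
    q = q_from_radius(r_mm, wavelength, distance_mm)
    az = np.degrees(np.arctan2(np.broadcast_to(dy, q.shape),
                               np.broadcast_to(dx, q.shape))) % 360.0
    return q, az, r_px
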