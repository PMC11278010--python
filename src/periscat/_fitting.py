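"""Small shared fitting helpers (1D Gaussian peaks on scattered samples)."""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def gaussian_const(x, amplitude, center, sigma, offset):
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2) + offset


def fit_gaussian_peak(x, y, min_points: int = 6):
    """Least-squares Gaussian + constant fit on scattered (x, y) samples.

    Returns a dict with center, center_err, sigma, fwhm, amplitude, offset,
    or ``None`` when the data are insufficient or the optimizer fails. Used
    for per-sector radial peaks (ring-point extraction, geometry
    calibration); the main (002) analysis peak fit lives in
    :mod:`periscat.xrd` and uses lmfit with a linear background.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    if x.size < min_points:
        return None
    offset0 = float(np.min(y))
    w = y - offset0
    w_sum = float(np.sum(w))
    if w_sum <= 0:
        return None
    center0 = float(np.sum(x * w) / w_sum)
    var0 = float(np.sum(w * (x - center0) ** 2) / w_sum)
    sigma0 = np.sqrt(max(var0, 1e-12))
    amp0 = float(np.max(y) - offset0)
    if amp0 <= 0:
        return None
    try:
        popt, pcov = curve_fit(
            gaussian_const, x, y, p0=[amp0, center0, sigma0, offset0],
            maxfev=4000)
    except (RuntimeError, ValueError):
        return None
    amplitude, center, sigma, offset = popt
    sigma = abs(float(sigma))
    if amplitude <= 0 or not (x.min() <= center <= x.max()):
        return None
    perr = np.sqrt(np.abs(np.diag(pcov)))
    return {
        "center": float(center),
        "center_err": float(perr[1]),
        "sigma": sigma,
        "fwhm": FWHM_PER_SIGMA * sigma,
        "fwhm_err": FWHM_PER_SIGMA * float(perr[2]),
        "amplitude": float(amplitude),
        "offset": float(offset),
    }
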