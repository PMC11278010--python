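"""Wide-angle stage: (002) peak fitting, Bragg d-spacing, Scherrer size.

Per scan point, the hydroxyapatite (002) Bragg peak is fit with a Gaussian
plus linear background on the azimuthally integrated profile; the fitted
center gives the lattice spacing through Bragg's law (n lambda = 2 d sin
theta) and the fitted FWHM gives the crystallite size through the Scherrer
equation (tau = K lambda / (beta cos theta)). Conventions:

* beta is the peak FWHM expressed in radians on the 2-theta axis; the
  fitted q-width is converted to 2-theta exactly (difference of the angles
  at the two half-maximum q positions), not by a small-angle derivative.
* K defaults to 1.0 ("shape factor close to 1"); no instrumental broadening
  is subtracted by default, with optional quadrature subtraction
  ``beta^2 = beta_obs^2 - beta_instr^2``.

Uncertainties are 1-sigma values propagated to first order from the fit
covariance. Quality control never raises per point: failed fits and
low-quality fits are flagged in the record table and the map carries NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lmfit.models import GaussianModel, LinearModel

from ._fitting import FWHM_PER_SIGMA
from .frames import DetectorFrame
from .geometry import ExperimentGeometry, bragg_d_from_q, two_theta_from_q
from .reduction import RadialProfile, azimuthal_integrate


@dataclass
class PeakFitResult:
    """Gaussian + linear-background fit of one Bragg peak in q coordinates."""

    center_q: float
    center_sigma_q: float
    fwhm_q: float
    fwhm_sigma_q: float
    amplitude: float
    background: dict
    r_squared: float
    converged: bool
    window: tuple[float, float] = (np.nan, np.nan)
    n_points: int = 0
    at_window_edge: bool = False

    def center_two_theta(self, wavelength: float) -> float:
        return float(two_theta_from_q(self.center_q, wavelength))

    def fwhm_two_theta(self, wavelength: float) -> float:
        """Peak FWHM converted exactly to the 2-theta axis (radians)."""
        lo = two_theta_from_q(self.center_q - self.fwhm_q / 2.0, wavelength)
        hi = two_theta_from_q(self.center_q + self.fwhm_q / 2.0, wavelength)
        return float(hi - lo)


def _failed_fit(window, n_points=0) -> PeakFitResult:
    return PeakFitResult(center_q=np.nan, center_sigma_q=np.nan,
                         fwhm_q=np.nan, fwhm_sigma_q=np.nan,
                         amplitude=np.nan, background={}, r_squared=0.0,
                         converged=False, window=tuple(window),
                         n_points=n_points)


def fit_002_peak(profile: RadialProfile,
                 window: tuple[float, float],
                 use_weights: bool = True) -> PeakFitResult:
    """Fit a Gaussian + linear background to the peak inside ``window`` (q).

    When the profile carries per-bin uncertainties (all positive inside the
    window) and ``use_weights`` is set, the fit minimizes the
    uncertainty-weighted residual, which keeps the reported center/width
    uncertainties honest under counting noise. Never raises on optimizer
    failure: the result carries ``converged=False`` instead, so scanning
    maps keep going. A window outside the profile support, however, is a
    caller error and raises.
    """
    lo, hi = map(float, window)
    v = profile.valid
    if lo >= profile.q[v].max() or hi <= profile.q[v].min():
        raise ValueError(
            f"fit window {window} lies outside the profile q-range "
            f"[{profile.q[v].min():.3f}, {profile.q[v].max():.3f}]")
    sel = v & (profile.q >= lo) & (profile.q <= hi)
    q = profile.q[sel]
    y = profile.intensity[sel]
    weights = None
    if use_weights:
        s = profile.sigma[sel]
        if np.all(np.isfinite(s)) and np.all(s > 0):
            weights = 1.0 / s
    if q.size < 8:
        return _failed_fit(window, n_points=int(q.size))
    model = GaussianModel(prefix="g_") + LinearModel(prefix="bg_")
    imax = int(np.argmax(y))
    base = float(np.median(np.concatenate([y[:3], y[-3:]])))
    amp0 = max(float(y[imax] - base), 1e-12)
    halfmax = base + amp0 / 2.0
    above = q[y >= halfmax]
    fwhm0 = float(above.max() - above.min()) if above.size >= 2 else (hi - lo) / 10.0
    sigma0 = max(fwhm0 / FWHM_PER_SIGMA, (q[1] - q[0]))
    params = model.make_params(
        g_center=float(q[imax]), g_sigma=sigma0,
        g_amplitude=amp0 * sigma0 * np.sqrt(2.0 * np.pi),
        bg_slope=0.0, bg_intercept=base)
    try:
        out = model.fit(y, params, x=q, weights=weights)
    except Exception:
        return _failed_fit(window, n_points=int(q.size))
    if not out.success:
        return _failed_fit(window, n_points=int(q.size))
    p = out.params
    center = float(p["g_center"].value)
    fwhm = float(FWHM_PER_SIGMA * p["g_sigma"].value)
    center_err = p["g_center"].stderr
    fwhm_err = p["g_sigma"].stderr
    ss_res = float(np.sum(out.residual ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    edge_margin = 0.02 * (hi - lo)
    return PeakFitResult(
        center_q=center,
        center_sigma_q=float(center_err) if center_err is not None else 0.0,
        fwhm_q=fwhm,
        fwhm_sigma_q=float(FWHM_PER_SIGMA * fwhm_err) if fwhm_err is not None else 0.0,
        amplitude=float(p["g_height"].value),
        background={"slope": float(p["bg_slope"].value),
                    "intercept": float(p["bg_intercept"].value)},
        r_squared=r2,
        converged=bool(fwhm > 0 and lo <= center <= hi),
        window=(lo, hi),
        n_points=int(q.size),
        at_window_edge=bool(center < lo + edge_margin or center > hi - edge_margin),
    )


def bragg_d_spacing(fit: PeakFitResult, wavelength: float,
                    order: int = 1) -> tuple[float, float]:
    """Lattice spacing d = n lambda / (2 sin theta) with 1-sigma uncertainty.

    Expressed through the fitted q-center, d = 2 pi n / q; the uncertainty
    follows from first-order propagation of the center uncertainty,
    sigma_d = d * sigma_q / q. The wavelength enters only the preconditions
    (the fitted center must be representable), not the value.
    """
    if not fit.converged:
        raise ValueError("cannot convert a non-converged peak fit")
    if order < 1:
        raise ValueError("diffraction order must be >= 1")
    if fit.center_q <= 0:
        raise ValueError("non-positive peak center (sin theta = 0)")
    two_theta_from_q(fit.center_q, wavelength)  # representability check
    d = float(bragg_d_from_q(fit.center_q, order))
    sigma = d * fit.center_sigma_q / fit.center_q
    return d, float(sigma)


def scherrer_size(fit: PeakFitResult, wavelength: float, K: float = 1.0,
                  instrumental_fwhm_2theta: float = 0.0) -> tuple[float, float]:
    """Crystallite size tau = K lambda / (beta cos theta), 1-sigma uncertainty.

    ``beta`` is the fitted FWHM on the 2-theta axis (exact q-to-angle
    conversion). When an instrumental FWHM is supplied it is removed in
    quadrature before applying the Scherrer relation, which can only
    increase the estimate. Uncertainty is propagated from the fitted width
    uncertainty only.
    """
    if not fit.converged:
        raise ValueError("cannot convert a non-converged peak fit")
    if not 0.8 < K <= 1.2:
        raise ValueError("Scherrer shape factor K expected in (0.8, 1.2]")
    beta_obs = fit.fwhm_two_theta(wavelength)
    if beta_obs <= 0:
        raise ValueError("non-positive peak width")
    if instrumental_fwhm_2theta >= beta_obs:
        raise ValueError(
            "instrumental broadening exceeds the observed width; "
            "crystallite size is unresolvable")
    beta = np.sqrt(beta_obs ** 2 - instrumental_fwhm_2theta ** 2)
    theta = fit.center_two_theta(wavelength) / 2.0
    tau = K * wavelength / (beta * np.cos(theta))
    # d(2theta)/dq at the center converts the q-width uncertainty exactly
    # enough at first order.
    dtt_dq = wavelength / (2.0 * np.pi * np.cos(theta))
    sigma_beta_obs = fit.fwhm_sigma_q * dtt_dq
    sigma_tau = tau * beta_obs * sigma_beta_obs / beta ** 2
    return float(tau), float(sigma_tau)


@dataclass
class UltrastructureConfig:
    """Settings for per-scan-point (002) analysis.

    The fit window defaults to +/- ``window_fwhm_factor`` expected FWHMs
    around the nominal (002) position computed from the d-spacing prior
    (2 pi / d_prior) and the crystallite-size prior, which automates the
    "well-isolated peak" window choice reproducibly.
    """

    d_prior_nm: float = 0.344
    tau_prior_nm: float = 30.0
    window_fwhm_factor: float = 5.0
    window: Optional[tuple[float, float]] = None
    scherrer_K: float = 1.0
    diffraction_order: int = 1
    instrumental_fwhm_2theta: float = 0.0
    qc_r_squared: float = 0.75
    n_bins: int = 3000
    q_range: Optional[tuple[float, float]] = None

    def fit_window(self, wavelength: float) -> tuple[float, float]:
        if self.window is not None:
            return self.window
        q0 = 2.0 * np.pi / self.d_prior_nm
        theta = float(two_theta_from_q(q0, wavelength)) / 2.0
        beta = self.scherrer_K * wavelength / (self.tau_prior_nm * np.cos(theta))
        fwhm_q = beta * 2.0 * np.pi * np.cos(theta) / wavelength
        half = self.window_fwhm_factor * fwhm_q
        return (q0 - half, q0 + half)


def analyze_profile(profile: RadialProfile, wavelength: float,
                    config: UltrastructureConfig) -> dict:
    """One-point XRD analysis: peak fit -> (d, tau) with QC flags."""
    flags = []
    rec = {"d_spacing_nm": np.nan, "d_sigma_nm": np.nan,
           "crystallite_nm": np.nan, "crystallite_sigma_nm": np.nan,
           "r_squared": np.nan, "converged": False, "qc_pass": False}
    try:
        fit = fit_002_peak(profile, config.fit_window(wavelength))
    except ValueError as exc:
        rec["flags"] = f"window_error:{exc}"
        return rec
    rec["r_squared"] = fit.r_squared
    rec["converged"] = fit.converged
    if not fit.converged:
        flags.append("fit_failed")
    else:
        d, ds = bragg_d_spacing(fit, wavelength, config.diffraction_order)
        tau, ts = scherrer_size(fit, wavelength, config.scherrer_K,
                                config.instrumental_fwhm_2theta)
        rec.update(d_spacing_nm=d, d_sigma_nm=ds, crystallite_nm=tau,
                   crystallite_sigma_nm=ts)
        if fit.r_squared < config.qc_r_squared:
            flags.append("low_r_squared")
        if fit.at_window_edge:
            flags.append("center_at_window_edge")
    rec["qc_pass"] = fit.converged and not flags
    rec["flags"] = ";".join(flags)
    return rec


def map_ultrastructure(frames: Sequence[DetectorFrame],
                       geometry: ExperimentGeometry,
                       config: Optional[UltrastructureConfig] = None,
                       ) -> pd.DataFrame:
    """Per-scan-point (002) analysis over a frame collection.

    Returns one record per frame with scan position (from frame metadata),
    d-spacing and crystallite size with uncertainties, fit diagnostics and
    QC flags. Frames that cannot be integrated (e.g. fully masked) yield
    flagged records; the map never aborts on a single bad point.
    """
    config = config or UltrastructureConfig()
    records = []
    for i, frame in enumerate(frames):
        rec = {"index": i,
               "x_mm": frame.metadata.get("x_mm", np.nan),
               "y_mm": frame.metadata.get("y_mm", np.nan)}
        try:
            profile = azimuthal_integrate(frame, geometry,
                                          n_bins=config.n_bins,
                                          q_range=config.q_range)
            rec.update(analyze_profile(profile, geometry.wavelength, config))
        except ValueError as exc:
            rec.update({"d_spacing_nm": np.nan, "d_sigma_nm": np.nan,
                        "crystallite_nm": np.nan, "crystallite_sigma_nm": np.nan,
                        "r_squared": np.nan, "converged": False,
                        "qc_pass": False, "flags": f"integration_error:{exc}"})
        records.append(rec)
    return pd.DataFrame(records)
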