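"""Small-angle stage: T-parameter (mineral platelet thickness) per scan point.

For an ideal two-phase material the stack-of-cards definition
``T = 4 phi (1 - phi) / sigma_v`` (phi: mineral volume fraction, sigma_v:
interface area per volume) has the standard experimental realization

    T = (4 / pi) * Q / P,

with ``Q = integral q^2 I(q) dq`` (scattering invariant) and
``P = lim q^4 I(q)`` (Porod constant). The estimator works on the Kratky
curve ``q^2 I(q)``:

* the measured invariant is extended below the first bin by a q^2 rise of
  the Kratky curve (continuity) and above the last bin by the fitted Porod
  tail;
* P comes from a weighted linear fit of ``q^4 I`` against
  ``[1, q^-2]`` (constant Porod term plus the leading deviation) over the
  upper fit range, with an optional flat incoherent background term
  (``B q^4``) for noisy data.

Quality control mirrors the wide-angle stage: a fit-quality score in [0, 1]
(fraction of Kratky-curve variance explained over the Porod range) with a
configurable threshold, flags instead of exceptions per point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .reduction import RadialProfile


def kratky_transform(profile: RadialProfile) -> RadialProfile:
    """Pointwise Kratky transform: (q, q^2 I, q^2 sigma), order preserved."""
    if np.any(profile.q <= 0):
        raise ValueError("Kratky transform requires strictly positive q")
    return RadialProfile(q=profile.q.copy(),
                         intensity=profile.q ** 2 * profile.intensity,
                         sigma=profile.q ** 2 * profile.sigma,
                         n_pixels=profile.n_pixels.copy(),
                         azimuth_range=profile.azimuth_range)


def t_from_invariants(invariant_q: float, porod_constant: float) -> float:
    """Stack-of-cards platelet thickness T = (4/pi) Q / P."""
    return 4.0 / np.pi * invariant_q / porod_constant


@dataclass
class KratkyFit:
    """Invariant/Porod analysis of one SAXS profile."""

    invariant_q: float
    porod_constant: float
    t_parameter_nm: float
    fit_quality: float
    qc_pass: bool
    extrapolation: dict
    n_negative_excluded: int = 0
    flags: str = ""


@dataclass
class TParameterConfig:
    """Settings for the Kratky/Porod T-parameter estimator."""

    q_fit_range: Optional[tuple[float, float]] = None  # Porod fit range, nm^-1
    porod_fraction: float = 0.3   # top fraction of q used when range not given
    fit_background: bool = False  # flat incoherent background term
    qc_threshold: float = 0.75
    porod_window_warn: float = 8.0  # warn when q_max * T below this


def fit_t_parameter(profile: RadialProfile,
                    q_fit_range: Optional[tuple[float, float]] = None,
                    config: Optional[TParameterConfig] = None) -> KratkyFit:
    """Estimate the T-parameter of one profile via the Kratky plot.

    Negative-intensity bins are excluded (and counted); a non-positive
    Porod estimate is a flagged failure, never an exception.
    """
    config = config or TParameterConfig()
    if q_fit_range is None:
        q_fit_range = config.q_fit_range
    v = profile.valid & np.isfinite(profile.intensity)
    q = profile.q[v]
    I = profile.intensity[v]
    s = profile.sigma[v]
    neg = I < 0
    n_neg = int(np.count_nonzero(neg))
    q, I, s = q[~neg], I[~neg], s[~neg]
    if q.size < 10:
        return KratkyFit(np.nan, np.nan, np.nan, 0.0, False, {},
                         n_neg, flags="too_few_bins")
    if q_fit_range is None:
        q_fit_range = (q[-1] * (1.0 - config.porod_fraction), q[-1])
    lo, hi = q_fit_range
    if lo < q[0] or hi > q[-1] * (1 + 1e-9):
        raise ValueError(
            f"Porod fit range {q_fit_range} outside profile support "
            f"[{q[0]:.4g}, {q[-1]:.4g}]")
    por = (q >= lo) & (q <= hi)
    qp, Ip, sp = q[por], I[por], s[por]
    y = qp ** 4 * Ip
    cols = [np.ones_like(qp), qp ** -2.0]
    if config.fit_background:
        cols.append(qp ** 4)
    A = np.column_stack(cols)
    w = np.ones_like(qp)
    if np.all(sp > 0):
        w = 1.0 / (qp ** 4 * sp)
    sol, *_ = np.linalg.lstsq(A * w[:, None], y * w, rcond=None)
    porod_p = float(sol[0])
    porod_c = float(sol[1])
    background = float(sol[2]) if config.fit_background else 0.0
    if porod_p <= 0:
        return KratkyFit(np.nan, porod_p, np.nan, 0.0, False,
                         {"porod_range": (float(lo), float(hi))},
                         n_neg, flags="non_positive_porod")
    # fit quality: Kratky-curve variance explained over the Porod range
    kratky = qp ** 2 * Ip
    model_kratky = (A @ sol) / qp ** 2
    ss_res = float(np.sum((kratky - model_kratky) ** 2))
    ss_tot = float(np.sum((kratky - kratky.mean()) ** 2))
    quality = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0)) if ss_tot > 0 else 1.0

    I_coh = I - background
    J = q ** 2 * I_coh
    q_measured = float(np.trapezoid(J, q))
    low_q = float(J[0] * q[0] / 3.0)          # q^2 rise of the Kratky curve
    tail = float(porod_p / q[-1] + porod_c / (3.0 * q[-1] ** 3))
    invariant = q_measured + low_q + tail
    t_nm = t_from_invariants(invariant, porod_p)
    flags = []
    if t_nm > 0 and q[-1] * t_nm < config.porod_window_warn:
        warnings.warn(
            f"Porod regime barely reached: q_max * T = {q[-1] * t_nm:.2f} "
            f"< {config.porod_window_warn}", stacklevel=2)
        flags.append("short_porod_window")
    qc = bool(quality >= config.qc_threshold and t_nm > 0)
    if quality < config.qc_threshold:
        flags.append("low_fit_quality")
    return KratkyFit(
        invariant_q=float(invariant), porod_constant=porod_p,
        t_parameter_nm=float(t_nm), fit_quality=quality, qc_pass=qc,
        extrapolation={"low_q_term": low_q, "high_q_term": tail,
                       "porod_deviation_coeff": porod_c,
                       "background": background,
                       "porod_range": (float(lo), float(hi))},
        n_negative_excluded=n_neg,
        flags=";".join(flags))


def t_parameter_map(profiles: Mapping[tuple[float, float], RadialProfile],
                    records: pd.DataFrame,
                    config: Optional[TParameterConfig] = None,
                    ) -> pd.DataFrame:
    """Merge per-scan-point T-parameter fits into an ultrastructure table.

    ``profiles`` maps scan position (x_mm, y_mm) to the point's SAXS
    profile; every record position must have a profile (missing keys are
    reported collectively). QC-failed points carry NaN T and a flag.
    """
    config = config or TParameterConfig()
    keys = list(zip(records["x_mm"].round(9), records["y_mm"].round(9)))
    lookup = {(round(float(x), 9), round(float(y), 9)): p
              for (x, y), p in profiles.items()}
    missing = [k for k in keys if k not in lookup]
    if missing:
        raise ValueError(f"missing SAXS profiles for scan positions: "
                         f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    t, qual, qc, fl = [], [], [], []
    for k in keys:
        fit = fit_t_parameter(lookup[k], config=config)
        t.append(fit.t_parameter_nm if fit.qc_pass else np.nan)
        qual.append(fit.fit_quality)
        qc.append(fit.qc_pass)
        fl.append(fit.flags)
    out = records.copy()
    out["t_parameter_nm"] = t
    out["t_fit_quality"] = qual
    out["t_qc_pass"] = qc
    out["t_flags"] = fl
    return out
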