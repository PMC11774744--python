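"""Four-parameter log-logistic (LL.4) dose-response fitting and IC50.

The model is ``f(x) = lower + (upper - lower) / (1 + (x/e)**slope)`` with
dose ``x`` in micromolar. With ``slope > 0`` the response decreases with
dose, which is the convention for viability assays. ``e`` is the
inflection concentration — the *relative* IC50. The *absolute* IC50 is the
dose where the fitted viability crosses 0.5, solved in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class DoseResponseFit:
    lower: float
    upper: float
    slope: float
    e_param: float
    rss: float
    converged: bool


def loglogistic4(x, lower, upper, slope, e):
    x = np.asarray(x, dtype=float)
    return lower + (upper - lower) / (1.0 + (x / e) ** slope)


def fit_loglogistic4(doses, responses, init: Optional[dict] = None) -> DoseResponseFit:
    """Bounded least-squares fit of the LL.4 model.

    Requires at least 5 distinct positive doses (4 parameters + 1).
    Triplicate wells enter as individual points. A fit with a collapsed
    response range (``upper`` not above ``lower``) is flagged
    ``converged=False`` rather than raising.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if not np.all(np.isfinite(responses)):
        raise ValueError("responses must be finite")
    if np.unique(doses).size < 5:
        raise ValueError("need at least 5 distinct positive doses to fit "
                         "4 parameters")

    rmin, rmax = responses.min(), responses.max()
    span = rmax - rmin
    mid = 0.5 * (rmin + rmax)
    if init is None:
        init = {}
    e0 = init.get("e_param", doses[int(np.argmin(np.abs(responses - mid)))])
    x0 = np.array([
        init.get("lower", rmin),
        init.get("upper", rmax),
        init.get("slope", 1.0),
        np.log(e0),
    ])
    lo = [rmin - 2 * span - 1e-9, rmin - 2 * span - 1e-9, -50.0,
          np.log(doses.min()) - 10]
    hi = [rmax + 2 * span + 1e-9, rmax + 2 * span + 1e-9, 50.0,
          np.log(doses.max()) + 10]
    x0 = np.clip(x0, lo, hi)

    logx = np.log(doses)

    def resid(p):
        lower, upper, slope, loge = p
        return lower + (upper - lower) / (1.0 + np.exp(slope * (logx - loge))) - responses

    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=20000)
    lower, upper, slope, loge = sol.x
    rss = float(np.sum(sol.fun ** 2))
    degenerate = (upper - lower) <= max(1e-8, 1e-6 * max(span, 1.0)) or abs(slope) < 1e-6
    return DoseResponseFit(lower=float(lower), upper=float(upper),
                           slope=float(slope), e_param=float(np.exp(loge)),
                           rss=rss, converged=bool(sol.success and not degenerate))


def ic50(fit: DoseResponseFit, scale: str = "relative") -> float:
    """IC50 in micromolar from a converged LL.4 fit.

    ``relative`` returns the inflection concentration ``e``; ``absolute``
    solves ``f(x) = 0.5`` and raises if 0.5 lies outside the open interval
    (lower, upper) — no extrapolation.
    """
    if not fit.converged:
        raise ValueError("IC50 requested from a non-converged fit")
    if scale == "relative":
        return fit.e_param
    if scale != "absolute":
        raise ValueError(f"unknown IC50 scale {scale!r}")
    lo, hi = sorted((fit.lower, fit.upper))
    if not (lo < 0.5 < hi):
        raise ValueError(
            f"absolute IC50 undefined: 0.5 outside fitted asymptotes "
            f"({fit.lower:.4g}, {fit.upper:.4g})")
    # 0.5 = lower + (upper-lower)/(1+(x/e)^s)  =>  (x/e)^s = (upper-0.5)/(0.5-lower)
    ratio = (fit.upper - 0.5) / (0.5 - fit.lower)
    return float(fit.e_param * ratio ** (1.0 / fit.slope))


def fit_plate(plate: pd.DataFrame, scale: str = "relative") -> pd.DataFrame:
    """Fit every (sample, drug) group of a plate table.

    Expects columns ``sample_id, drug, dose_um, viability``; returns one
    row per group with the fitted parameters and IC50 (NaN when the fit is
    degenerate or the absolute IC50 undefined).
    """
    required = {"sample_id", "drug", "dose_um", "viability"}
    if not required.issubset(plate.columns):
        raise ValueError(f"plate table must have columns {sorted(required)}")
    rows = []
    for (sample, drug), grp in plate.groupby(["sample_id", "drug"], sort=False):
        fit = fit_loglogistic4(grp["dose_um"], grp["viability"])
        try:
            value = ic50(fit, scale=scale)
        except ValueError:
            value = np.nan
        rows.append({"sample_id": sample, "drug": drug, "lower": fit.lower,
                     "upper": fit.upper, "slope": fit.slope,
                     "e_param": fit.e_param, "rss": fit.rss,
                     "converged": fit.converged, "ic50_um": value})
    return pd.DataFrame(rows)
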