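"""Hill dose-response fitting: EC50, depth of response, concordance.

Mean SGR vs concentration is fitted to the four-parameter Hill model

    SGR(C) = Emax + (E0 - Emax) / (1 + (C / EC50)^HS)

with E0 the low-dose (untreated) asymptote, Emax the high-dose asymptote,
EC50 the inflection concentration and HS the Hill slope.  Depth of
response DoR = (E0 - Emax)/E0 exceeds 1 when the high-dose plateau shows
net mass loss.  EC50 is fitted on a log scale; HS may be fixed at 1 to
obtain the 3-parameter variant.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

log = logging.getLogger(__name__)

#: flags thresholds (statistical identifiability of the fitted curve)
_MAX_SE_LOG10_EC50 = 0.3   # > 2x multiplicative uncertainty on EC50
_MIN_R2 = 0.85
_MIN_SPAN_SE_RATIO = 4.0


def hill_model(c, e0: float, emax: float, ec50: float, hs: float):
    """Hill curve; returns E0 at C=0 and Emax as C -> infinity."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    with np.errstate(divide="ignore"):
        out = emax + (e0 - emax) / (1.0 + (c / ec50) ** hs)
    out = np.where(c == 0, e0, out)  # exact control value, no rounding
    return out if out.ndim else float(out)


def depth_of_response(e0: float, emax: float) -> float:
    """DoR = (E0 - Emax) / E0; NaN (flagged by caller) when E0 = 0."""
    if e0 == 0:
        log.warning("depth_of_response undefined: E0 = 0")
        return float("nan")
    return (e0 - emax) / e0


@dataclass
class HillFit:
    """Fitted Hill parameters, derived DoR and diagnostics."""

    e0: float
    emax: float
    ec50: float
    hs: float
    dor: float
    r2: float
    rmse: float
    se: dict = field(default_factory=dict)   # parameter standard errors
    flags: dict = field(default_factory=dict)
    doses: np.ndarray | None = None
    responses: np.ndarray | None = None

    @property
    def degenerate(self) -> bool:
        return bool(self.flags.get("degenerate", False))

    def predict(self, c):
        return hill_model(c, self.e0, self.emax, self.ec50, self.hs)

    def to_dict(self) -> dict:
        return {"e0": self.e0, "emax": self.emax, "ec50": self.ec50,
                "hs": self.hs, "dor": self.dor, "r2": self.r2,
                "rmse": self.rmse, "se": dict(self.se),
                "flags": dict(self.flags)}


def fit_hill(doses, mean_sgrs, sem=None, fix_hs: float | None = None
             ) -> HillFit:
    """Nonlinear least-squares Hill fit to per-condition mean SGRs.

    ``doses`` may include 0 (vehicle control), handled analytically by the
    model.  ``sem`` (per-point standard errors) weights the fit and makes
    parameter uncertainties absolute.  The returned fit is always
    populated; pathological data are flagged (``flags['degenerate']``)
    rather than raised.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(mean_sgrs, dtype=float)
    if doses.shape != y.shape or doses.ndim != 1:
        raise ValueError("doses and responses must be matching 1D arrays")
    if len(np.unique(doses)) < 4:
        raise ValueError("need >= 4 distinct doses")
    pos = doses[doses > 0]
    lo, hi = np.log10(pos.min() / 100.0), np.log10(pos.max() * 100.0)

    # standard initialization: asymptotes from the dose extremes,
    # EC50 from the geometric mid-dose, HS = 1
    order = np.argsort(doses)
    e0_0, emax_0 = y[order[0]], y[order[-1]]
    lec_0 = float(np.log10(np.sqrt(pos.min() * pos.max())))
    sigma = None
    if sem is not None:
        sigma = np.clip(np.asarray(sem, dtype=float), 1e-12, None)

    if fix_hs is None:
        def model(c, e0, emax, lec, hs):
            return hill_model(c, e0, emax, 10.0 ** lec, hs)
        p0 = [e0_0, emax_0, lec_0, 1.0]
        bounds = ([-1.0, -1.0, lo, 0.05], [1.0, 1.0, hi, 10.0])
    else:
        def model(c, e0, emax, lec):
            return hill_model(c, e0, emax, 10.0 ** lec, fix_hs)
        p0 = [e0_0, emax_0, lec_0]
        bounds = ([-1.0, -1.0, lo], [1.0, 1.0, hi])

    flags = {"converged": True, "ec50_identifiable": True}
    try:
        popt, pcov = curve_fit(model, doses, y, p0=p0, bounds=bounds,
                               sigma=sigma, absolute_sigma=sigma is not None,
                               maxfev=20000)
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((len(p0), len(p0)), np.nan)
        flags["converged"] = False

    perr = np.sqrt(np.diag(pcov))
    e0, emax, lec = popt[0], popt[1], popt[2]
    hs = fix_hs if fix_hs is not None else popt[3]
    pred = model(doses, *popt)
    resid = y - pred
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0

    se = {"e0": float(perr[0]), "emax": float(perr[1]),
          "log10_ec50": float(perr[2])}
    if fix_hs is None:
        se["hs"] = float(perr[3])
    span = e0 - emax
    se_span = float(np.sqrt(pcov[0, 0] + pcov[1, 1] - 2 * pcov[0, 1])) \
        if np.isfinite(pcov[0, 0]) else np.nan

    at_bounds = (lec <= lo + 0.05) or (lec >= hi - 0.05)
    weak_span = (not np.isfinite(se_span)) or \
        (abs(span) <= _MIN_SPAN_SE_RATIO * se_span + 1e-15)
    wide_ec50 = (not np.isfinite(se["log10_ec50"])) or \
        (se["log10_ec50"] > _MAX_SE_LOG10_EC50)
    # DoR = (E0-Emax)/E0 needs a growing baseline: E0 must be positive and
    # statistically distinguishable from zero
    dor_defined = bool(np.isfinite(se["e0"]) and e0 > 2.0 * se["e0"])
    flags["ec50_identifiable"] = not (at_bounds or wide_ec50 or weak_span)
    flags["ec50_at_bounds"] = bool(at_bounds)
    flags["dor_defined"] = dor_defined
    flags["degenerate"] = bool(
        not flags["converged"] or at_bounds or wide_ec50 or weak_span
        or not dor_defined or r2 < _MIN_R2)
    if flags["degenerate"]:
        log.warning("Hill fit flagged degenerate: r2=%.3f se(logEC50)=%.3f",
                    r2, se["log10_ec50"])

    return HillFit(e0=float(e0), emax=float(emax), ec50=float(10.0 ** lec),
                   hs=float(hs), dor=depth_of_response(float(e0), float(emax)),
                   r2=r2, rmse=rmse, se=se, flags=flags,
                   doses=doses, responses=y)


def aggregate_sgr(sgr_df: pd.DataFrame) -> pd.DataFrame:
    """Pooled per-condition mean SGR with across-well SEM.

    Per (drug, dose): the mean pools all cells in the condition; SEM is the
    standard error of per-well means when >1 replicate well is present,
    else the pooled SEM across cells.
    """
    rows = []
    for (drug, dose), g in sgr_df.groupby(["drug", "dose"], sort=True):
        well_means = g.groupby("well")["sgr"].mean()
        if len(well_means) > 1:
            sem = float(well_means.std(ddof=1) / np.sqrt(len(well_means)))
        else:
            sem = float(g["sgr"].std(ddof=1) / np.sqrt(len(g))) if len(g) > 1 \
                else np.nan
        rows.append({"drug": drug, "dose": float(dose),
                     "mean_sgr": float(g["sgr"].mean()), "sem": sem,
                     "n_wells": int(len(well_means)), "n_cells": int(len(g))})
    return pd.DataFrame(rows)


def fit_hill_table(sgr_df: pd.DataFrame, fix_hs: float | None = None
                   ) -> dict[str, HillFit]:
    """Per-drug Hill fits from a tidy SGR table (aggregated internally)."""
    agg = aggregate_sgr(sgr_df)
    fits = {}
    for drug, g in agg.groupby("drug", sort=True):
        if drug == "" or len(g) < 4:
            continue
        sem = g["sem"].to_numpy()
        use_sem = np.all(np.isfinite(sem)) and np.all(sem > 0)
        fits[str(drug)] = fit_hill(g["dose"].to_numpy(),
                                   g["mean_sgr"].to_numpy(),
                                   sem=sem if use_sem else None,
                                   fix_hs=fix_hs)
    return fits


def concordance(x, y) -> float:
    """Lin's concordance correlation coefficient (population variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length paired series with n >= 3")
    vx, vy = x.var(), y.var()
    if vx + vy == 0:
        raise ValueError("concordance undefined for zero total variance")
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / denom)
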