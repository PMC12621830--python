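"""Temporal response dynamics and subpopulation structure.

Two analyses operate on windowed single-cell SGR distributions:

* **Time of response (ToR).**  Per window, the treated and control SGR
  samples are smoothed into densities (Gaussian KDE, fixed bandwidth
  0.0025 h^-1) and compared by the Hellinger distance
  H = sqrt(1 - integral sqrt(p q)).  H(t) is fitted with a saturating
  exponential H(t) = Hinf (1 - e^(-t/tau)); ToR is where the fitted curve
  crosses a threshold set by the maximum Hellinger distance between the
  two on-plate control groups.  If the fit never crosses within the
  observed time range the condition is reported as non-responsive.

* **Two-Gaussian mixture timecourse.**  Each window's KDE curve is fitted
  with y = A f exp(-((x-mu_s)/sigma_s)^2) + A (1-f) exp(-((x-mu_n)/sigma_n)^2),
  where the s (sensitive/responsive) component is the lower-SGR one and f
  its fraction.  Note the components are written with exp(-((x-mu)/sigma)^2),
  so sigma = sqrt(2) * the usual Gaussian standard deviation.  The first
  window is initialized from the KDE amplitude and the overall median /
  standard deviation; each later window warm-starts from the previous fit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import gaussian_kde

log = logging.getLogger(__name__)

DEFAULT_BANDWIDTH = 0.0025  # h^-1


@dataclass
class KDEParams:
    """Fixed-bandwidth Gaussian KDE settings."""

    bandwidth: float = DEFAULT_BANDWIDTH
    grid_points: int = 512
    pad_bandwidths: float = 4.0
    grid_min: float | None = None
    grid_max: float | None = None

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass
class HellingerSeries:
    """Hellinger distance vs window center with exponential fit and ToR."""

    window_centers_h: np.ndarray
    distances: np.ndarray
    threshold: float
    h_inf: float = float("nan")
    tau_h: float = float("nan")
    tor_h: float | None = None
    responded: bool = False
    fit_ok: bool = True


def _grid_for(samples_list, params: KDEParams) -> np.ndarray:
    lo = params.grid_min
    hi = params.grid_max
    if lo is None:
        lo = min(float(np.min(s)) for s in samples_list) \
            - params.pad_bandwidths * params.bandwidth
    if hi is None:
        hi = max(float(np.max(s)) for s in samples_list) \
            + params.pad_bandwidths * params.bandwidth
    return np.linspace(lo, hi, params.grid_points)


def kde_density(samples, params: KDEParams | None = None,
                grid: np.ndarray | None = None):
    """Gaussian-kernel density on a grid, normalized to integrate to 1.

    Returns (grid, density).  Degenerate all-equal samples produce a
    narrow peak at the common value with a warning.
    """
    params = params or KDEParams()
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for a density estimate")
    if grid is None:
        grid = _grid_for([x], params)
    sd = x.std(ddof=1)
    if sd == 0:
        log.warning("kde_density: degenerate all-equal samples")
        dens = np.exp(-0.5 * ((grid - x[0]) / params.bandwidth) ** 2)
    else:
        kde = gaussian_kde(x, bw_method=params.bandwidth / sd)
        dens = kde(grid)
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("density integrates to zero on this grid")
    return grid, dens / area


def hellinger_distance(p: np.ndarray, q: np.ndarray,
                       grid: np.ndarray) -> float:
    """Hellinger distance between two densities on a common grid, in [0,1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.shape != grid.shape:
        raise ValueError("densities and grid must share a shape")
    for name, d in (("p", p), ("q", q)):
        area = np.trapezoid(d, grid)
        if abs(area - 1.0) > 1e-6:
            log.warning("hellinger_distance: renormalizing %s (area=%.4g)",
                        name, area)
        if area <= 0:
            raise ValueError(f"density {name} integrates to zero")
    p = p / np.trapezoid(p, grid)
    q = q / np.trapezoid(q, grid)
    bc = np.trapezoid(np.sqrt(p * q), grid)
    return float(np.sqrt(np.clip(1.0 - bc, 0.0, 1.0)))


def hellinger_from_samples(a, b, params: KDEParams | None = None) -> float:
    """Hellinger distance between two sample sets via a shared-grid KDE."""
    params = params or KDEParams()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    grid = _grid_for([a, b], params)
    _, p = kde_density(a, params, grid)
    _, q = kde_density(b, params, grid)
    return hellinger_distance(p, q, grid)


def control_threshold(control_a: dict[float, np.ndarray],
                      control_b: dict[float, np.ndarray],
                      params: KDEParams | None = None) -> float:
    """Max Hellinger distance between the two on-plate control groups."""
    if not control_a or not control_b:
        raise ValueError("two non-empty control groups are required")
    centers = sorted(set(control_a) & set(control_b))
    if not centers:
        raise ValueError("control groups share no window centers")
    return max(hellinger_from_samples(control_a[c], control_b[c], params)
               for c in centers)


def _saturating_exp(t, h_inf, tau):
    return h_inf * (1.0 - np.exp(-t / tau))


def time_of_response(treated: dict[float, np.ndarray],
                     control: dict[float, np.ndarray],
                     threshold: float,
                     params: KDEParams | None = None) -> HellingerSeries:
    """Hellinger timecourse, saturating-exponential fit, and ToR.

    ToR is the analytic crossing time of the fitted curve with the
    threshold; it is reported only when the crossing falls within the
    observed window range, otherwise the condition is non-responsive.
    """
    centers = sorted(set(treated) & set(control))
    if len(centers) < 3:
        raise ValueError("need >= 3 common window centers")
    t = np.array(centers, dtype=float)
    h = np.array([hellinger_from_samples(treated[c], control[c], params)
                  for c in centers])

    series = HellingerSeries(window_centers_h=t, distances=h,
                             threshold=float(threshold))
    try:
        popt, _ = curve_fit(_saturating_exp, t, h,
                            p0=[max(h.max(), 1e-3), max(t.max() / 4.0, 1.0)],
                            bounds=([0.0, 1e-3], [1.2, 1e4]), maxfev=10000)
    except RuntimeError:
        series.fit_ok = False
        log.warning("time_of_response: exponential fit did not converge")
        return series
    series.h_inf, series.tau_h = float(popt[0]), float(popt[1])
    if series.h_inf > threshold > 0:
        tor = -series.tau_h * np.log(1.0 - threshold / series.h_inf)
        if tor <= t[-1]:
            series.tor_h = float(tor)
            series.responded = True
    elif threshold == 0 and series.h_inf > 0:
        series.tor_h = 0.0
        series.responded = True
    return series


# ---------------------------------------------------------------------------
# Two-Gaussian mixture over time
# ---------------------------------------------------------------------------

def _mixture_curve(x, A, f, mu_s, sigma_s, mu_n, sigma_n):
    return (A * f * np.exp(-((x - mu_s) / sigma_s) ** 2)
            + A * (1.0 - f) * np.exp(-((x - mu_n) / sigma_n) ** 2))


def fit_two_gaussians(grid: np.ndarray, density: np.ndarray,
                      init: dict | None = None) -> dict | None:
    """Fit a KDE curve with a sum of two Gaussians.

    Returns a dict (A, f, mu_s, sigma_s, mu_n, sigma_n, r2, identifiable)
    with the sensitive (lower-mean) component labeled ``s``; None when the
    optimizer fails.  When the components collapse onto each other
    (|mu_s - mu_n| < mean sigma) ``identifiable`` is False and f should
    not be interpreted.
    """
    x = np.asarray(grid, dtype=float)
    y = np.asarray(density, dtype=float)
    if init is None:
        w = y / y.sum()
        m_all = float(x[np.searchsorted(np.cumsum(w), 0.5)])  # weighted median
        s_all = float(np.sqrt(np.sum(w * (x - m_all) ** 2)))
        init = {"A": float(y.max()), "f": 0.5,
                "mu_s": m_all - s_all / 2.0, "sigma_s": s_all,
                "mu_n": m_all + s_all / 2.0, "sigma_n": s_all}
    span = x[-1] - x[0]
    p0 = [init["A"], min(max(init["f"], 1e-3), 1 - 1e-3),
          init["mu_s"], max(init["sigma_s"], span * 1e-4),
          init["mu_n"], max(init["sigma_n"], span * 1e-4)]
    bounds = ([0.0, 0.0, x[0], span * 1e-5, x[0], span * 1e-5],
              [y.max() * 10 + 1e-12, 1.0, x[-1], span, x[-1], span])
    p0 = np.clip(p0, bounds[0], bounds[1])
    try:
        popt, _ = curve_fit(_mixture_curve, x, y, p0=p0, bounds=bounds,
                            maxfev=20000)
    except RuntimeError:
        return None
    A, f, mu_s, sigma_s, mu_n, sigma_n = popt
    if mu_s > mu_n:  # relabel: sensitive = lower-SGR component
        mu_s, mu_n = mu_n, mu_s
        sigma_s, sigma_n = sigma_n, sigma_s
        f = 1.0 - f
    pred = _mixture_curve(x, A, f, mu_s, sigma_s, mu_n, sigma_n)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - pred) ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    identifiable = abs(mu_n - mu_s) >= 0.5 * (sigma_s + sigma_n)
    if not identifiable:
        log.info("mixture fit: components overlap; fraction unidentifiable")
    return {"A": float(A), "f": float(f), "mu_s": float(mu_s),
            "sigma_s": float(sigma_s), "mu_n": float(mu_n),
            "sigma_n": float(sigma_n), "r2": r2,
            "identifiable": bool(identifiable)}


def fit_mixture_sequence(samples_by_window: dict[float, np.ndarray],
                         params: KDEParams | None = None) -> pd.DataFrame:
    """Sequentially-initialized two-Gaussian fits over time windows.

    The first window is initialized from the KDE amplitude and the overall
    sample median/SD; each subsequent window warm-starts from the previous
    fit.  A failed fit carries the previous parameters forward and is
    flagged (``fit_failed``).  Columns include the non-responsive fraction
    (1 - f) plotted in resistance analyses.
    """
    params = params or KDEParams()
    centers = sorted(samples_by_window)
    if not centers:
        raise ValueError("no windows supplied")
    rows = []
    prev_fit: dict | None = None
    for c in centers:
        s = np.asarray(samples_by_window[c], dtype=float)
        grid, dens = kde_density(s, params)
        if prev_fit is None:
            m_all = float(np.median(s))
            s_all = float(np.std(s))
            init = {"A": float(dens.max()), "f": 0.5,
                    "mu_s": m_all - s_all / 2.0, "sigma_s": s_all,
                    "mu_n": m_all + s_all / 2.0, "sigma_n": s_all}
        else:
            init = {k: prev_fit[k]
                    for k in ("A", "f", "mu_s", "sigma_s", "mu_n", "sigma_n")}
        fit = fit_two_gaussians(grid, dens, init)
        failed = fit is None
        if failed:
            log.warning("mixture fit failed at window %.1f h; carrying "
                        "previous parameters", c)
            fit = prev_fit if prev_fit is not None else {
                "A": np.nan, "f": np.nan, "mu_s": np.nan, "sigma_s": np.nan,
                "mu_n": np.nan, "sigma_n": np.nan, "r2": np.nan,
                "identifiable": False}
        rows.append({"window_center_h": float(c), **{k: fit[k] for k in
                     ("A", "f", "mu_s", "sigma_s", "mu_n", "sigma_n", "r2",
                      "identifiable")},
                     "nonresponsive_fraction": 1.0 - fit["f"],
                     "n_cells": int(s.size), "fit_failed": failed})
        if not failed:
            prev_fit = fit
    return pd.DataFrame(rows)
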