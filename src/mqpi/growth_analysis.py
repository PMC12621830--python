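"""Specific growth rates, windowed SGR distributions, normalized mass
curves and mass-threshold filtering.

SGR is the slope of a least-squares line through the (median-filtered)
mass series divided by the fitted line's value at the start of the series
("initial projected mass"), giving a size-normalized rate in h^-1.  Only
tracks longer than 20 frames are fitted; the median filter (5 frames)
shrinks its window at the ends instead of padding.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CellTrack, tracks_to_frame

log = logging.getLogger(__name__)

DEFAULT_MEDIAN_WINDOW = 5
DEFAULT_MIN_LENGTH = 20      # tracks must be strictly longer than this
DEFAULT_WINDOW_WIDTH_H = 12.0
DEFAULT_WINDOW_STEP_H = 2.0


@dataclass
class SGRRecord:
    """Per-track specific growth rate and fit diagnostics."""

    track_id: int
    sgr: float                 # h^-1
    initial_mass_pg: float     # fitted line evaluated at track start
    fit_r2: float
    n_frames: int
    well: str = ""
    drug: str = ""
    dose: float = 0.0


@dataclass
class MassFilter:
    """Initial-mass threshold used to exclude contaminating cells."""

    threshold_pg: float
    side: str = "keep_above"   # or "keep_below"

    def __post_init__(self) -> None:
        if self.threshold_pg < 0:
            raise ValueError("threshold must be >= 0")
        if self.side not in ("keep_above", "keep_below"):
            raise ValueError("side must be keep_above or keep_below")


def median_filter_shrink(x: np.ndarray, window: int = DEFAULT_MEDIAN_WINDOW
                         ) -> np.ndarray:
    """Centered running median, shrinking symmetrically at the series ends.

    Near an end the half-width is reduced (no padding, no fabricated
    values), which keeps the window symmetric about each point; a linear
    series therefore passes through unchanged.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    half = (window - 1) // 2
    if n <= 2 * half:
        half = (n - 1) // 2
    out = np.empty(n)
    if n >= 2 * half + 1 and half > 0:
        sw = np.lib.stride_tricks.sliding_window_view(x, 2 * half + 1)
        out[half:n - half] = np.median(sw, axis=1)
    elif half == 0:
        return x.copy()
    for i in range(half):
        out[i] = np.median(x[: 2 * i + 1])
        out[n - 1 - i] = np.median(x[n - 1 - 2 * i:])
    return out


def _line_fit(t: np.ndarray, m: np.ndarray):
    """Least-squares line; returns slope, intercept, r2."""
    slope, intercept = np.polyfit(t, m, 1)
    pred = slope * t + intercept
    ss_res = float(((m - pred) ** 2).sum())
    ss_tot = float(((m - m.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


def compute_sgr(track: CellTrack,
                median_window: int = DEFAULT_MEDIAN_WINDOW,
                min_length: int = DEFAULT_MIN_LENGTH) -> SGRRecord | None:
    """SGR of one track, or None (with a logged reason) if too short."""
    if len(track) <= min_length:
        log.info("track %s skipped: %d frames <= %d",
                 track.track_id, len(track), min_length)
        return None
    m = median_filter_shrink(track.masses_pg, median_window)
    t = track.times_h
    slope, intercept, r2 = _line_fit(t, m)
    m0 = intercept + slope * t[0]
    if m0 == 0:
        return None
    return SGRRecord(track_id=track.track_id, sgr=float(slope / m0),
                     initial_mass_pg=float(m0), fit_r2=r2,
                     n_frames=len(track), well=track.well,
                     drug=track.drug, dose=track.dose)


def sgr_table(tracks: list[CellTrack],
              median_window: int = DEFAULT_MEDIAN_WINDOW,
              min_length: int = DEFAULT_MIN_LENGTH) -> pd.DataFrame:
    """SGR records for a track collection as a tidy DataFrame."""
    recs = [compute_sgr(tr, median_window, min_length) for tr in tracks]
    rows = [r.__dict__ for r in recs if r is not None]
    cols = ["track_id", "sgr", "initial_mass_pg", "fit_r2", "n_frames",
            "well", "drug", "dose"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Windowed SGR (time-resolved distributions)
# ---------------------------------------------------------------------------

def default_window_centers(duration_h: float,
                           width_h: float = DEFAULT_WINDOW_WIDTH_H,
                           step_h: float = DEFAULT_WINDOW_STEP_H) -> np.ndarray:
    """Window centers on a 2 h grid whose windows lie inside [0, duration]."""
    half = width_h / 2.0
    centers = np.arange(0.0, duration_h + step_h / 2, step_h)
    return centers[(centers - half >= -1e-9) &
                   (centers + half <= duration_h + 1e-9)]


def _mass_matrix(tracks: list[CellTrack], median_window: int):
    """Common time grid and per-cell median-filtered masses (NaN padded)."""
    grid = np.unique(np.concatenate([tr.times_h for tr in tracks]))
    M = np.full((len(tracks), grid.size), np.nan)
    for i, tr in enumerate(tracks):
        idx = np.searchsorted(grid, tr.times_h)
        M[i, idx] = median_filter_shrink(tr.masses_pg, median_window)
    return grid, M


def _windowed_slopes(grid: np.ndarray, M: np.ndarray, center: float,
                     width_h: float, track_t0: np.ndarray):
    """Vectorized per-cell line fits restricted to one window.

    The slope is normalized by the window fit's value extrapolated to each
    track's own start time — the "initial mass predicted by the linear
    fit", matching the whole-track SGR convention.  Cells with fewer than
    half the window's frames get NaN.
    """
    half = width_h / 2.0
    sel = (grid >= center - half) & (grid <= center + half)
    if not sel.any():
        return np.full(M.shape[0], np.nan), np.zeros(M.shape[0], dtype=int)
    t = grid[sel]
    sub = M[:, sel]
    valid = np.isfinite(sub)
    n = valid.sum(axis=1)
    need = max(int(np.ceil(sel.sum() / 2.0)), 2)

    w = valid.astype(float)
    sw = w.sum(axis=1)
    sw = np.where(sw > 0, sw, np.nan)
    tbar = (w * t).sum(axis=1) / sw
    mbar = np.nansum(np.where(valid, sub, 0.0), axis=1) / sw
    dt = (t[None, :] - tbar[:, None]) * w
    dm = np.where(valid, sub - mbar[:, None], 0.0)
    stt = (dt * dt).sum(axis=1)
    slope = np.where(stt > 0, (dt * dm).sum(axis=1) / np.where(stt > 0, stt, 1.0),
                     np.nan)
    m0 = mbar + slope * (track_t0 - tbar)
    # guard: a window fit whose back-extrapolated initial mass is not
    # clearly positive gives a meaningless normalization; exclude the cell
    sane = (mbar > 0) & (m0 > 0.05 * np.abs(mbar))
    sgr = np.where((n >= need) & sane, slope / np.where(sane, m0, 1.0), np.nan)
    return sgr, n


def windowed_sgr(tracks: list[CellTrack], centers=None,
                 width_h: float = DEFAULT_WINDOW_WIDTH_H,
                 median_window: int = DEFAULT_MEDIAN_WINDOW) -> pd.DataFrame:
    """Per-cell SGR within sliding windows (long format).

    Within each window [center - w/2, center + w/2] a line is fitted per
    cell and normalized by its value at the window's first covered
    timepoint, matching the whole-track SGR convention.  Cells present for
    fewer than half the window's frames are excluded.
    """
    if not tracks:
        return pd.DataFrame(columns=["window_center_h", "track_id", "sgr"])
    grid, M = _mass_matrix(tracks, median_window)
    if centers is None:
        centers = default_window_centers(float(grid[-1]), width_h)
    ids = np.array([tr.track_id for tr in tracks])
    track_t0 = np.array([tr.times_h[0] for tr in tracks])
    out = []
    for c in np.atleast_1d(centers):
        sgr, _ = _windowed_slopes(grid, M, float(c), width_h, track_t0)
        ok = np.isfinite(sgr)
        out.append(pd.DataFrame({"window_center_h": float(c),
                                 "track_id": ids[ok], "sgr": sgr[ok]}))
    frames = [f for f in out if not f.empty]
    if not frames:
        return pd.DataFrame(columns=["window_center_h", "track_id", "sgr"])
    return pd.concat(frames, ignore_index=True)


def windowed_sgr_samples(tracks: list[CellTrack], centers=None,
                         width_h: float = DEFAULT_WINDOW_WIDTH_H,
                         median_window: int = DEFAULT_MEDIAN_WINDOW
                         ) -> dict[float, np.ndarray]:
    """Windowed SGR as {window center: per-cell sample array}."""
    df = windowed_sgr(tracks, centers, width_h, median_window)
    return {float(c): g["sgr"].to_numpy()
            for c, g in df.groupby("window_center_h", sort=True)}


# ---------------------------------------------------------------------------
# Population curves and mass filtering
# ---------------------------------------------------------------------------

def normalized_mass_curve(tracks: list[CellTrack]) -> pd.DataFrame:
    """Total population mass per timepoint divided by its initial value.

    SEM is computed across wells when tracks carry >1 well label (biological
    replicates), otherwise across cells.
    """
    df = tracks_to_frame(tracks)
    wells = df["well"].unique()
    if len(wells) > 1:
        per = df.pivot_table(index="time_h", columns="well", values="mass_pg",
                             aggfunc="sum")
        per = per / per.iloc[0]
        mean = per.mean(axis=1)
        sem = per.std(axis=1, ddof=1) / np.sqrt(per.shape[1])
    else:
        per = df.pivot_table(index="time_h", columns="track_id",
                             values="mass_pg", aggfunc="sum")
        norm = per.sum(axis=1) / per.sum(axis=1).iloc[0]
        rel = per / per.iloc[0]
        mean = norm
        sem = rel.std(axis=1, ddof=1) / np.sqrt(rel.shape[1])
    if float(mean.iloc[0]) <= 0:
        raise ValueError("initial total mass must be positive")
    return pd.DataFrame({"time_h": mean.index.to_numpy(),
                         "mass_norm": mean.to_numpy(),
                         "sem": sem.to_numpy()})


def apply_mass_filter(records: pd.DataFrame, filt: MassFilter
                      ) -> tuple[pd.DataFrame, dict]:
    """Split SGR records on initial mass; returns (retained, summary)."""
    m = records["initial_mass_pg"].to_numpy(float)
    keep = m > filt.threshold_pg if filt.side == "keep_above" \
        else m <= filt.threshold_pg
    kept, removed = records[keep], records[~keep]
    if kept.empty:
        log.warning("mass filter at %.3g pg removed every record",
                    filt.threshold_pg)
    summary = {
        "threshold_pg": filt.threshold_pg, "side": filt.side,
        "n_retained": int(len(kept)), "n_removed": int(len(removed)),
        "mean_sgr_retained": float(kept["sgr"].mean()) if len(kept) else np.nan,
        "mean_sgr_removed": float(removed["sgr"].mean()) if len(removed) else np.nan,
    }
    return kept.reset_index(drop=True), summary


def suggest_mass_threshold(initial_masses_pg: np.ndarray,
                           min_prominence: float = 0.05) -> float | None:
    """Antimode of a two-component fit to the log10 initial-mass KDE.

    Mode candidates come from peak detection on the smoothed density
    (prominence >= ``min_prominence`` of the tallest peak); a two-Gaussian
    fit initialized at the two most prominent modes refines the antimode
    between them.  Returns None for unimodal inputs, in which case no
    automatic threshold is proposed.
    """
    from scipy.signal import find_peaks

    from .heterogeneity import KDEParams, fit_two_gaussians, kde_density

    x = np.log10(np.asarray(initial_masses_pg, dtype=float))
    x = x[np.isfinite(x)]
    if x.size < 10:
        return None
    # Silverman bandwidth on the log scale
    bw = 0.9 * min(x.std(ddof=1), (np.quantile(x, 0.75) - np.quantile(x, 0.25)) / 1.34)
    bw = max(bw * x.size ** (-0.2), 1e-3)
    grid, dens = kde_density(x, KDEParams(bandwidth=bw))
    peaks, props = find_peaks(dens, prominence=min_prominence * dens.max())
    if len(peaks) < 2:
        return None
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    lo_pk, hi_pk = np.sort(grid[top2])
    between = (grid > lo_pk) & (grid < hi_pk)
    if not between.any():
        return None
    antimode = float(grid[between][np.argmin(dens[between])])

    init = {"A": float(dens.max()),
            "f": float(dens[grid <= antimode].sum() / dens.sum()),
            "mu_s": float(lo_pk), "sigma_s": bw * 3,
            "mu_n": float(hi_pk), "sigma_n": bw * 3}
    fit = fit_two_gaussians(grid, dens, init)
    if fit is not None and fit["identifiable"]:
        lo, hi = sorted((fit["mu_s"], fit["mu_n"]))
        sel = (grid > lo) & (grid < hi)
        if sel.any():
            model = (fit["A"] * fit["f"]
                     * np.exp(-((grid - fit["mu_s"]) / fit["sigma_s"]) ** 2)
                     + fit["A"] * (1 - fit["f"])
                     * np.exp(-((grid - fit["mu_n"]) / fit["sigma_n"]) ** 2))
            antimode = float(grid[sel][np.argmin(model[sel])])
    return float(10.0 ** antimode)
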