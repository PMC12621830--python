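"""Core data containers shared across the pipeline.

Units are fixed package-wide: space in micrometres, time in hours, mass in
picograms, phase in radians, specific growth rate (SGR) in h^-1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order for per-frame cell observation tables.
OBS_COLUMNS = [
    "frame", "time_h", "label", "x_um", "y_um",
    "area_um2", "mass_pg", "mean_phase", "well", "position",
]

#: Canonical column order for track tables (long format, one row per
#: observation, ``track_id`` groups rows into tracks).
TRACK_COLUMNS = [
    "track_id", "frame", "time_h", "x_um", "y_um", "mass_pg",
    "well", "drug", "dose",
]


@dataclass
class PhaseFrame:
    """A 2D quantitative phase map (radians) at one position and timepoint."""

    phase: np.ndarray
    pixel_size_um: float
    wavelength_nm: float
    frame: int = 0
    time_h: float = 0.0
    position: str = ""
    well: str = ""

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValueError("phase must be a 2D array")
        if self.pixel_size_um <= 0 or self.wavelength_nm <= 0:
            raise ValueError("pixel_size_um and wavelength_nm must be positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape


@dataclass
class CellTrack:
    """An ordered mass/position time series for one cell.

    ``meta`` carries generator ground truth (true SGR, subpopulation) or
    tracker QC information; it is never required by downstream analysis.
    """

    track_id: int
    frames: np.ndarray
    times_h: np.ndarray
    masses_pg: np.ndarray
    x_um: np.ndarray | None = None
    y_um: np.ndarray | None = None
    well: str = ""
    drug: str = ""
    dose: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.masses_pg = np.asarray(self.masses_pg, dtype=float)
        n = len(self.frames)
        if n < 1:
            raise ValueError("a track needs at least one observation")
        if len(self.times_h) != n or len(self.masses_pg) != n:
            raise ValueError("frames, times and masses must have equal length")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_h(self) -> float:
        return float(self.times_h[-1] - self.times_h[0])


def tracks_to_frame(tracks: list[CellTrack]) -> pd.DataFrame:
    """Flatten a list of tracks into a long-format table (TRACK_COLUMNS)."""
    rows = []
    for tr in tracks:
        n = len(tr)
        x = tr.x_um if tr.x_um is not None else np.full(n, np.nan)
        y = tr.y_um if tr.y_um is not None else np.full(n, np.nan)
        rows.append(pd.DataFrame({
            "track_id": tr.track_id, "frame": tr.frames, "time_h": tr.times_h,
            "x_um": x, "y_um": y, "mass_pg": tr.masses_pg,
            "well": tr.well, "drug": tr.drug, "dose": tr.dose,
        }))
    if not rows:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(rows, ignore_index=True)[TRACK_COLUMNS]


def frame_to_tracks(df: pd.DataFrame) -> list[CellTrack]:
    """Inverse of :func:`tracks_to_frame`."""
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(CellTrack(
            track_id=int(tid),
            frames=g["frame"].to_numpy(),
            times_h=g["time_h"].to_numpy(),
            masses_pg=g["mass_pg"].to_numpy(),
            x_um=g["x_um"].to_numpy() if "x_um" in g else None,
            y_um=g["y_um"].to_numpy() if "y_um" in g else None,
            well=str(g["well"].iloc[0]) if "well" in g else "",
            drug=str(g["drug"].iloc[0]) if "drug" in g else "",
            dose=float(g["dose"].iloc[0]) if "dose" in g else 0.0,
        ))
    return tracks
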