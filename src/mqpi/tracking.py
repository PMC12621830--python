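"""Frame-to-frame cell linking and track assembly.

Observations in consecutive frames are paired by a globally optimal
assignment (Hungarian algorithm) on the combined cost

    c = spatial_weight * ||dxy||^2 + mass_weight * (dm)^2

with gates on displacement and relative mass jump; gated-out cells start
or terminate tracks.  Default weights normalize each term to 1 at its
gate so position and mass contribute comparably.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .datatypes import TRACK_COLUMNS

_INF = 1e12
#: cost of leaving a cell unlinked, in gate-normalized units: slightly above
#: half the worst admissible link so any admissible link beats birth+death.
_NO_LINK = 1.05


@dataclass
class LinkCost:
    """Metric and gates for frame-to-frame linking."""

    spatial_weight: float | None = None   # um^-2; None -> 1/max_link^2
    mass_weight: float | None = None      # pg^-2; None -> auto from gate
    max_link_distance_um: float = 15.0
    max_mass_jump_frac: float = 0.5
    max_gap_frames: int = 0

    def __post_init__(self) -> None:
        if self.spatial_weight is not None and self.spatial_weight < 0:
            raise ValueError("weights must be >= 0")
        if self.mass_weight is not None and self.mass_weight < 0:
            raise ValueError("weights must be >= 0")
        if (self.spatial_weight == 0 and self.mass_weight == 0):
            raise ValueError("spatial and mass weights cannot both be zero")


def _weights(cost: LinkCost, masses: np.ndarray) -> tuple[float, float]:
    sw = cost.spatial_weight
    mw = cost.mass_weight
    if sw is None:
        sw = 1.0 / cost.max_link_distance_um ** 2
    if mw is None:
        ref = np.median(masses) if masses.size else 1.0
        gate = max(cost.max_mass_jump_frac * max(ref, 1e-9), 1e-9)
        mw = 1.0 / gate ** 2
    return sw, mw


def link_frames(obs_a: pd.DataFrame, obs_b: pd.DataFrame,
                cost: LinkCost | None = None) -> list[tuple[int, int]]:
    """Optimal one-to-one assignment between two observation tables.

    Returns (row position in obs_a, row position in obs_b) pairs; cells
    beyond the distance or mass-jump gates are left unassigned.  Uses the
    augmented-matrix linear assignment formulation so births and deaths
    compete with links on cost.
    """
    cost = cost or LinkCost()
    na, nb = len(obs_a), len(obs_b)
    if na == 0 or nb == 0:
        return []
    xa = obs_a[["x_um", "y_um"]].to_numpy(float)
    xb = obs_b[["x_um", "y_um"]].to_numpy(float)
    ma = obs_a["mass_pg"].to_numpy(float)
    mb = obs_b["mass_pg"].to_numpy(float)

    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
    dm = ma[:, None] - mb[None, :]
    jump = np.abs(dm) / np.maximum(np.abs(ma[:, None]), 1e-9)
    sw, mw = _weights(cost, np.concatenate([ma, mb]))
    C = sw * d2 + mw * dm ** 2
    inadmissible = (np.sqrt(d2) > cost.max_link_distance_um) | \
                   (jump > cost.max_mass_jump_frac)
    C = np.where(inadmissible, _INF, C)

    # Jaqaman-style augmented square matrix: [[C, death], [birth, eps C^T]]
    A = np.full((na + nb, na + nb), _INF)
    A[:na, :nb] = C
    A[np.arange(na), nb + np.arange(na)] = _NO_LINK
    A[na + np.arange(nb), np.arange(nb)] = _NO_LINK
    lower_right = np.where(inadmissible.T, _INF, 1e-9)
    A[na:, nb:] = lower_right
    rows, cols = linear_sum_assignment(A)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if r < na and c < nb and A[r, c] < _INF]


def build_tracks(observations: pd.DataFrame,
                 cost: LinkCost | None = None) -> tuple[pd.DataFrame, dict]:
    """Assemble tracks from a multi-frame observation table.

    Returns the observation table with a ``track_id`` column (TRACK_COLUMNS
    layout) and a QC summary.  With ``max_gap_frames`` > 0, a track missing
    from up to that many consecutive frames may resume.
    """
    cost = cost or LinkCost()
    obs = observations.copy().reset_index(drop=True)
    if obs.empty:
        return pd.DataFrame(columns=TRACK_COLUMNS), {"n_tracks": 0}
    frames = np.sort(obs["frame"].unique())
    obs["track_id"] = -1
    next_id = 0
    # active: track_id -> (frame last seen, row index of last observation)
    active: dict[int, tuple[int, int]] = {}

    for fi, f in enumerate(frames):
        cur_idx = obs.index[obs["frame"] == f].to_numpy()
        cur = obs.loc[cur_idx]
        # candidates: tracks seen within the gap window
        cand_ids = [tid for tid, (lf, _) in active.items()
                    if f - lf <= 1 + cost.max_gap_frames]
        prev_rows = [active[tid][1] for tid in cand_ids]
        prev = obs.loc[prev_rows] if prev_rows else obs.iloc[0:0]
        links = link_frames(prev, cur, cost) if len(prev) and len(cur) else []
        linked_b = set()
        for ia, ib in links:
            tid = cand_ids[ia]
            obs.loc[cur_idx[ib], "track_id"] = tid
            active[tid] = (int(f), int(cur_idx[ib]))
            linked_b.add(ib)
        for ib in range(len(cur)):
            if ib not in linked_b:
                obs.loc[cur_idx[ib], "track_id"] = next_id
                active[next_id] = (int(f), int(cur_idx[ib]))
                next_id += 1
        # retire tracks that fell outside the gap window
        active = {tid: v for tid, v in active.items()
                  if f - v[0] <= 1 + cost.max_gap_frames}

    sizes = obs.groupby("track_id").size()
    qc = {
        "n_tracks": int(sizes.size),
        "n_observations": int(len(obs)),
        "median_track_length": float(sizes.median()),
        "n_full_length": int((sizes == len(frames)).sum()),
    }
    for col, default in (("well", ""), ("drug", ""), ("dose", 0.0)):
        if col not in obs:
            obs[col] = default
    return obs[TRACK_COLUMNS + [c for c in ("label", "position")
                                if c in obs]], qc
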