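"""Configuration, orchestration, file I/O and statistics utilities.

A run is fully determined by a :class:`RunConfig` (serializable to YAML;
its SHA-256 hash is stamped into every artifact) plus the inputs for the
configured entry level: raw half-circle intensities, phase stacks,
detection tables, mass tracks, or a seeded simulation.  Later stages are
shared: SGR -> optional mass filter -> per-drug Hill fit -> ToR ->
optional mixture timecourse, summarized in one machine-readable JSON.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import stats

from . import growth_analysis as ga
from . import heterogeneity as het
from .datatypes import CellTrack, frame_to_tracks, tracks_to_frame
from .dose_response import fit_hill_table
from .synthetic_data import DrugEffectSpec, PopulationSpec, simulate_tracks

log = logging.getLogger(__name__)

ENTRY_LEVELS = ("simulate", "tracks", "phase", "intensity")


@dataclass
class WellSpec:
    """Dosing description of one plate well."""

    drug: str = ""
    dose: float = 0.0
    dose_units: str = "uM"
    vehicle: str = "DMSO"
    control_group: str = ""
    n_positions: int = 9


@dataclass
class PlateMap:
    """Well -> condition mapping for one plate.

    Control wells have ``drug == ""`` and a ``control_group`` tag; ToR
    calibration requires at least two distinct tags.  The vehicle fraction
    (0.1% by default) is recorded for provenance.
    """

    wells: dict[str, WellSpec] = field(default_factory=dict)
    vehicle_fraction: float = 0.001

    def __post_init__(self) -> None:
        self.wells = {w: s if isinstance(s, WellSpec) else WellSpec(**s)
                      for w, s in self.wells.items()}

    @property
    def control_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for w, s in self.wells.items():
            if s.drug == "" and s.control_group:
                groups.setdefault(s.control_group, []).append(w)
        return groups

    def validate_for_tor(self) -> None:
        if len(self.control_groups) < 2:
            raise ValueError("ToR needs >= 2 control-group tags on the plate")

    def well_of_position(self, position: str) -> str:
        well = position.rsplit("_p", 1)[0]
        if well not in self.wells:
            raise KeyError(f"position {position!r} maps to no plate-map well")
        return well

    def validate_positions(self, positions) -> None:
        missing = sorted({p for p in positions
                          if p.rsplit("_p", 1)[0] not in self.wells})
        if missing:
            raise ValueError(
                "positions without plate-map wells: " + ", ".join(missing))

    def to_dict(self) -> dict:
        return {"vehicle_fraction": self.vehicle_fraction,
                "wells": {w: asdict(s) for w, s in sorted(self.wells.items())}}

    @classmethod
    def from_yaml(cls, path) -> "PlateMap":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(wells=d.get("wells", {}),
                   vehicle_fraction=d.get("vehicle_fraction", 0.001))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    entry: str = "tracks"
    seed: int = 0
    output_dir: str | None = None
    plate_map: PlateMap = field(default_factory=PlateMap)
    # stage toggles
    do_dose_response: bool = True
    do_tor: bool = True
    do_mixture: bool = False
    do_mass_filter: bool = False
    # stage parameters
    optics: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    link_cost: dict = field(default_factory=dict)
    sgr_median_window: int = ga.DEFAULT_MEDIAN_WINDOW
    sgr_min_length: int = ga.DEFAULT_MIN_LENGTH
    window_width_h: float = ga.DEFAULT_WINDOW_WIDTH_H
    window_step_h: float = ga.DEFAULT_WINDOW_STEP_H
    kde_bandwidth: float = het.DEFAULT_BANDWIDTH
    fix_hs: float | None = None
    mass_filter_threshold_pg: float | None = None  # None -> automatic
    # simulation entry: population + per-drug effect specs
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entry not in ENTRY_LEVELS:
            raise ValueError(f"entry must be one of {ENTRY_LEVELS}")
        if not isinstance(self.plate_map, PlateMap):
            self.plate_map = PlateMap(**self.plate_map)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["plate_map"] = self.plate_map.to_dict()
        return d

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # where results land doesn't change them
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_phase_tiff(path, stack: np.ndarray, pixel_size_um: float,
                     wavelength_nm: float) -> None:
    """32-bit float phase TIFF with scaling metadata in the description."""
    meta = json.dumps({"pixel_size_um": pixel_size_um,
                       "wavelength_nm": wavelength_nm, "units": "radians"})
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack", description=meta)


def read_phase_tiff(path):
    """Returns (stack float32, metadata dict)."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    return stack, meta


def write_tracks_csv(path, tracks: list[CellTrack]) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks_csv(path) -> list[CellTrack]:
    return frame_to_tracks(pd.read_csv(path, keep_default_na=False,
                                       na_values=[""]))


def write_json(path, obj) -> None:
    """Canonical (sorted, fixed-format) JSON for byte-stable artifacts."""
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# Statistics utilities
# ---------------------------------------------------------------------------

def standard_tests(group_a, group_b, alpha: float = 0.05) -> dict:
    """Welch two-tailed t-test on means and two-tailed F-test on variances."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
    F = a.var(ddof=1) / b.var(ddof=1)
    dfa, dfb = len(a) - 1, len(b) - 1
    f_p = 2.0 * min(stats.f.cdf(F, dfa, dfb), stats.f.sf(F, dfa, dfb))
    return {"t_stat": float(t_stat), "t_p": float(t_p),
            "t_significant": bool(t_p < alpha),
            "f_stat": float(F), "f_p": float(min(f_p, 1.0)),
            "f_significant": bool(f_p < alpha),
            "alpha": alpha, "n_a": len(a), "n_b": len(b)}


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

def _simulate_plate(config: RunConfig) -> list[CellTrack]:
    """Generate tracks for every plate-map well from the simulation spec."""
    sim = config.simulation
    pop_kw = dict(sim.get("population", {}))
    drugs = {name: DrugEffectSpec(**kw)
             for name, kw in sim.get("drugs", {}).items()}
    rng = np.random.default_rng(config.seed)
    tracks: list[CellTrack] = []
    offset = 0
    for well in sorted(config.plate_map.wells):
        spec = config.plate_map.wells[well]
        pop = PopulationSpec(**pop_kw)
        drug = drugs.get(spec.drug) if spec.drug else None
        well_tracks = simulate_tracks(pop, drug=drug, dose=spec.dose,
                                      rng=rng, well=well,
                                      drug_name=spec.drug)
        for tr in well_tracks:
            tr.track_id += offset
        offset += len(well_tracks)
        tracks.extend(well_tracks)
    return tracks


def _tor_tables(tracks, config: RunConfig) -> tuple[float, list[dict]]:
    """Control threshold and per-(drug, dose) ToR rows."""
    config.plate_map.validate_for_tor()
    kde = het.KDEParams(bandwidth=config.kde_bandwidth)
    centers = None  # derived per group from data duration
    groups = config.plate_map.control_groups
    tags = sorted(groups)[:2]
    by_well: dict[str, list[CellTrack]] = {}
    for tr in tracks:
        by_well.setdefault(tr.well, []).append(tr)

    def group_windows(wells):
        sel = [tr for w in wells for tr in by_well.get(w, [])]
        return ga.windowed_sgr_samples(sel, centers, config.window_width_h,
                                       config.sgr_median_window)

    ctrl_a = group_windows(groups[tags[0]])
    ctrl_b = group_windows(groups[tags[1]])
    threshold = het.control_threshold(ctrl_a, ctrl_b, kde)
    ctrl_all = group_windows(groups[tags[0]] + groups[tags[1]])

    rows = []
    conditions = sorted({(tr.drug, tr.dose) for tr in tracks if tr.drug})
    for drug, dose in conditions:
        sel = [tr for tr in tracks if tr.drug == drug and tr.dose == dose]
        treated = ga.windowed_sgr_samples(sel, centers, config.window_width_h,
                                          config.sgr_median_window)
        common = {c: treated[c] for c in treated if c in ctrl_all}
        if len(common) < 3:
            continue
        series = het.time_of_response(common,
                                      {c: ctrl_all[c] for c in common},
                                      threshold, kde)
        rows.append({"drug": drug, "dose": dose,
                     "tor_h": series.tor_h, "responded": series.responded,
                     "h_inf": series.h_inf, "tau_h": series.tau_h,
                     "fit_ok": series.fit_ok})
    return threshold, rows


def run_pipeline(config: RunConfig, inputs=None) -> dict:
    """Execute the configured stages and return the summary bundle.

    ``inputs`` depends on the entry level: None for ``simulate``, a tracks
    CSV path / DataFrame / list of CellTrack for ``tracks``, a list of
    :class:`~mqpi.datatypes.PhaseFrame` plus per-frame well labels for
    ``phase``, or a dict of four intensity stacks for ``intensity``.
    If ``config.output_dir`` is set, the summary and intermediate tables
    are written there.
    """
    if config.entry == "simulate":
        tracks = _simulate_plate(config)
    elif config.entry == "tracks":
        if isinstance(inputs, (str, Path)):
            tracks = read_tracks_csv(inputs)
        elif isinstance(inputs, pd.DataFrame):
            tracks = frame_to_tracks(inputs)
        else:
            tracks = list(inputs)
    elif config.entry in ("phase", "intensity"):
        from .cell_detection import SegmentationParams, detect_cells
        from .phase_reconstruction import OpticsSpec, reconstruct_from_intensities
        from .tracking import LinkCost, build_tracks
        frames = inputs
        if config.entry == "intensity":
            optics = OpticsSpec(**config.optics)
            frames = []
            for t in range(inputs["top"].shape[0]):
                pf = reconstruct_from_intensities(
                    inputs["top"][t], inputs["bottom"][t],
                    inputs["left"][t], inputs["right"][t], optics)
                pf.frame = t
                pf.time_h = t * inputs.get("frame_interval_h", 1 / 3)
                frames.append(pf)
        seg = SegmentationParams(**config.segmentation)
        obs = pd.concat([detect_cells(f, seg) for f in frames],
                        ignore_index=True)
        if obs.empty:
            raise ValueError("no cells detected at the phase entry level")
        config.plate_map.validate_positions(
            [p for p in obs["position"].unique() if p])
        tracked, qc = build_tracks(obs, LinkCost(**config.link_cost))
        tracks = frame_to_tracks(tracked)
        log.info("tracking: %s", qc)
    else:  # pragma: no cover - guarded by RunConfig
        raise ValueError(config.entry)

    summary: dict = {"config_hash": config.config_hash, "seed": config.seed,
                     "entry": config.entry,
                     "counts": {"n_tracks": len(tracks)}}

    sgr = ga.sgr_table(tracks, config.sgr_median_window, config.sgr_min_length)
    summary["counts"]["n_sgr_records"] = int(len(sgr))
    summary["counts"]["n_tracks_dropped_short"] = len(tracks) - len(sgr)

    if config.do_mass_filter and len(sgr):
        thr = config.mass_filter_threshold_pg
        if thr is None:
            thr = ga.suggest_mass_threshold(sgr["initial_mass_pg"].to_numpy())
        if thr is not None:
            sgr, filt_summary = ga.apply_mass_filter(
                sgr, ga.MassFilter(threshold_pg=float(thr)))
            summary["mass_filter"] = filt_summary
        else:
            summary["mass_filter"] = {"threshold_pg": None,
                                      "note": "no bimodal structure found"}

    if config.do_dose_response and len(sgr):
        fits = fit_hill_table(sgr, fix_hs=config.fix_hs)
        summary["dose_response"] = {d: f.to_dict() for d, f in fits.items()}

    if config.do_tor:
        threshold, rows = _tor_tables(tracks, config)
        summary["tor"] = {"threshold": threshold, "conditions": rows}

    if config.do_mixture:
        kde = het.KDEParams(bandwidth=config.kde_bandwidth)
        mix = {}
        for drug, dose in sorted({(tr.drug, tr.dose)
                                  for tr in tracks if tr.drug}):
            sel = [tr for tr in tracks
                   if tr.drug == drug and tr.dose == dose]
            windows = ga.windowed_sgr_samples(sel, None,
                                              config.window_width_h,
                                              config.sgr_median_window)
            windows = {c: s for c, s in windows.items() if s.size >= 10}
            if len(windows) < 2:
                continue
            tc = het.fit_mixture_sequence(windows, kde)
            mix[f"{drug}@{dose:g}"] = tc.to_dict(orient="list")
        summary["mixture"] = mix

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tracks_csv(out / "tracks.csv", tracks)
        sgr.to_csv(out / "sgr.csv", index=False)
        write_json(out / "summary.json", summary)
    return summary
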