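"""Seeded synthetic inputs for every pipeline entry level.

Three generators mirror the acquisition chain of a 96-well QPI drug
screen (9 positions/well, one frame every 20 min for 48 h):

* :func:`simulate_tracks` — single-cell dry-mass time series with
  Hill-model dose dependence, exponential response onset, resistant and
  non-growing subpopulations, and per-frame mass noise;
* :func:`render_phase_movie` — phase image stacks with ground-truth masks
  and identities for the mass/segmentation/tracking stages;
* :func:`render_dpc_intensities` — four half-circle intensity stacks via
  the same weak-object transfer functions the inverse solver uses.

All randomness flows through a single :class:`numpy.random.Generator`, so
identical specs + seed give bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_detection import MassConstants
from .datatypes import CellTrack
from .dose_response import hill_model
from .phase_reconstruction import AXES, OpticsSpec, transfer_functions


@dataclass
class MassComponent:
    """One component of the initial-mass mixture.

    ``sgr`` overrides the population control rate for cells of this
    component (e.g. 0.0 for non-growing contaminants); ``drug_responsive``
    False makes the component ignore the drug entirely, emulating
    non-tumor cells in direct-from-thaw samples.
    """

    weight: float
    mean_pg: float
    sd_pg: float
    sgr: float | None = None
    drug_responsive: bool = True


@dataclass
class PopulationSpec:
    """Statistical description of one simulated cell population."""

    n_cells: int = 200
    initial_mass_mix: tuple = ((1.0, 300.0, 75.0),)
    sgr_control: float = 0.02          # h^-1, vehicle-control growth rate
    sgr_sd: float = 0.005              # h^-1, per-cell biological spread
    noise_sd_mass: float = 1.0         # pg additive noise per frame
    frame_interval_h: float = 1.0 / 3.0
    duration_h: float = 48.0
    mass_distribution: str = "lognormal"  # or "normal"
    linear_growth: bool = False        # exact-line toggle for SGR tests
    seed: int | None = None

    def __post_init__(self) -> None:
        self.initial_mass_mix = tuple(
            c if isinstance(c, MassComponent) else MassComponent(*c)
            for c in self.initial_mass_mix)
        w = sum(c.weight for c in self.initial_mass_mix)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.frame_interval_h <= 0 or self.duration_h <= 0:
            raise ValueError("frame_interval and duration must be positive")
        if any(c.sd_pg < 0 for c in self.initial_mass_mix) or self.sgr_sd < 0 \
                or self.noise_sd_mass < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.mass_distribution not in ("lognormal", "normal"):
            raise ValueError("mass_distribution must be 'lognormal' or 'normal'")


@dataclass
class DrugEffectSpec:
    """Generative counterpart of the Hill dose-response model.

    e0/emax are the low/high-dose SGR asymptotes, ec50 the inflection
    concentration, hs the Hill slope.  ``response_delay_tau_h`` is the
    exponential onset timescale of the drug effect; resistant cells (drawn
    with probability ``resistant_fraction``) keep ``resistant_sgr``
    regardless of dose.
    """

    e0: float = 0.02
    emax: float = -0.01
    ec50: float = 0.1
    hs: float = 1.0
    response_delay_tau_h: float = 0.0
    resistant_fraction: float = 0.0
    resistant_sgr: float = 0.02

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if not 0.0 <= self.resistant_fraction <= 1.0:
            raise ValueError("resistant_fraction must lie in [0, 1]")


def _sample_initial_masses(pop: PopulationSpec, rng: np.random.Generator):
    comps = pop.initial_mass_mix
    weights = np.array([c.weight for c in comps])
    idx = rng.choice(len(comps), size=pop.n_cells, p=weights)
    m0 = np.empty(pop.n_cells)
    for i, c in enumerate(comps):
        sel = idx == i
        n = int(sel.sum())
        if n == 0:
            continue
        if pop.mass_distribution == "lognormal" and c.sd_pg > 0:
            # moment-matched lognormal: same mean and sd as requested
            s2 = np.log1p((c.sd_pg / c.mean_pg) ** 2)
            mu = np.log(c.mean_pg) - s2 / 2.0
            m0[sel] = rng.lognormal(mu, np.sqrt(s2), size=n)
        else:
            m0[sel] = np.clip(rng.normal(c.mean_pg, c.sd_pg, size=n),
                              c.mean_pg * 0.05, None)
    return m0, idx


def simulate_tracks(pop: PopulationSpec, drug: DrugEffectSpec | None = None,
                    dose: float = 0.0,
                    rng: np.random.Generator | None = None,
                    well: str = "", drug_name: str = "") -> list[CellTrack]:
    """Simulate single-cell mass tracks for one well/condition.

    Each cell draws a target SGR: resistant cells keep
    ``drug.resistant_sgr``; non-responsive mass components keep their own
    baseline; all others sit on the Hill curve at ``dose`` (the control
    rate when untreated).  The drug effect turns on as (1 - e^(-t/tau)),
    mass grows as m0*exp(g_eff(t)*t) (or the linear analogue), and
    per-frame additive Gaussian noise is applied last.
    """
    if drug is None:
        drug = DrugEffectSpec(e0=pop.sgr_control)
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if rng is None:
        rng = np.random.default_rng(pop.seed)

    times = np.arange(0.0, pop.duration_h + pop.frame_interval_h / 2,
                      pop.frame_interval_h)
    frames = np.arange(len(times))
    m0, comp_idx = _sample_initial_masses(pop, rng)
    comps = pop.initial_mass_mix

    base = np.array([c.sgr if c.sgr is not None else pop.sgr_control
                     for c in comps])[comp_idx]
    responsive = np.array([c.drug_responsive for c in comps])[comp_idx]
    resistant = rng.random(pop.n_cells) < drug.resistant_fraction
    resistant &= responsive

    jitter = rng.normal(0.0, pop.sgr_sd, size=pop.n_cells)
    g_drug = np.where(
        resistant, drug.resistant_sgr,
        np.where(responsive,
                 hill_model(dose, drug.e0, drug.emax, drug.ec50, drug.hs)
                 if dose > 0 else base,
                 base))
    g_base = np.where(resistant, drug.resistant_sgr, base)
    g_drug = g_drug + jitter
    g_base = g_base + jitter

    tau = drug.response_delay_tau_h
    if tau > 0:
        onset = 1.0 - np.exp(-times / tau)
    else:
        onset = np.ones_like(times)
    # g_eff(t): baseline rate relaxing to the dosed rate with timescale tau
    g_eff = g_base[:, None] + (g_drug - g_base)[:, None] * onset[None, :]

    if pop.linear_growth:
        masses = m0[:, None] * (1.0 + g_eff * times[None, :])
    else:
        masses = m0[:, None] * np.exp(g_eff * times[None, :])
    if pop.noise_sd_mass > 0:
        masses = masses + rng.normal(0.0, pop.noise_sd_mass, size=masses.shape)

    subpop = np.where(resistant, "resistant",
                      np.where(responsive, "responsive", "bystander"))
    tracks = []
    for i in range(pop.n_cells):
        tracks.append(CellTrack(
            track_id=i, frames=frames, times_h=times, masses_pg=masses[i],
            well=well, drug=drug_name, dose=dose,
            meta={"true_sgr": float(g_drug[i]), "initial_mass_pg": float(m0[i]),
                  "subpopulation": str(subpop[i]),
                  "component": int(comp_idx[i])}))
    return tracks


def sample_sgr_mixture(n: int, nonresponsive_fraction: float,
                       mu_responsive: float, mu_nonresponsive: float,
                       sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Draw SGR values from a two-Gaussian responsive/non-responsive mix."""
    if not 0.0 <= nonresponsive_fraction <= 1.0:
        raise ValueError("nonresponsive_fraction must lie in [0, 1]")
    nonresp = rng.random(n) < nonresponsive_fraction
    mu = np.where(nonresp, mu_nonresponsive, mu_responsive)
    return rng.normal(mu, sigma)


def bandlimited_phase(shape: tuple[int, int], optics: OpticsSpec,
                      rng: np.random.Generator,
                      band: tuple[float, float] = (0.35, 0.9),
                      amplitude_rad: float = 0.3) -> np.ndarray:
    """Random weak-phase test object band-limited to the DPC passband.

    White noise is filtered to an annulus ``band`` (fractions of the pupil
    cutoff NA/lambda) with cosine-tapered edges.  DPC has a null at DC, so
    a round-trip test object must carry its energy at mid frequencies; the
    default band keeps |H|^2 well above the default Tikhonov beta.
    """
    fy = np.fft.fftfreq(shape[0], d=optics.pixel_size_um)
    fx = np.fft.fftfreq(shape[1], d=optics.pixel_size_um)
    rho = np.hypot(*np.meshgrid(fy, fx, indexing="ij")) / optics.cutoff_um
    lo, hi = band
    taper = 0.1
    mask = np.clip((rho - lo) / taper, 0, 1) * np.clip((hi - rho) / taper, 0, 1)
    spec = np.fft.fft2(rng.normal(size=shape)) * mask
    phi = np.fft.ifft2(spec).real
    phi -= phi.mean()
    return phi * (amplitude_rad / np.abs(phi).max())


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Geometry and rendering options for synthetic phase movies.

    Defaults describe a 10x/0.25 NA system (0.6 um pixels, 525 nm) with
    uniform-disk cells placed with a minimum separation and moving by a
    bounded Gaussian random walk, so that segmentation and tracking have a
    well-posed ground truth.
    """

    image_shape: tuple[int, int] = (600, 600)
    pixel_size_um: float = 0.6
    wavelength_nm: float = 525.0
    cell_radius_um_mean: float = 7.0
    cell_radius_um_sd: float = 0.8
    phase_profile: str = "uniform-disk"  # or "gaussian-blob"
    background_phase_sd: float = 0.0
    motion_step_um: float = 1.0
    motion_bound_um: float = 5.0
    min_separation_um: float = 30.0
    margin_um: float = 12.0
    supersample: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.phase_profile not in ("uniform-disk", "gaussian-blob"):
            raise ValueError("unknown phase_profile")
        if self.cell_radius_um_mean * 2 >= min(self.image_shape) * self.pixel_size_um:
            raise ValueError("cell radius does not fit in the image")


@dataclass
class RenderedMovie:
    """Phase stack plus ground truth emitted by the renderer."""

    phase: np.ndarray            # (T, H, W) float32 radians
    labels: np.ndarray           # (T, H, W) uint16 ground-truth identities
    truth: pd.DataFrame          # cell_id, frame, x_um, y_um, mass_pg, ...
    scene: SceneSpec

    def phase_frames(self):
        from .datatypes import PhaseFrame
        return [PhaseFrame(self.phase[t], self.scene.pixel_size_um,
                           self.scene.wavelength_nm, frame=t)
                for t in range(self.phase.shape[0])]


def _place_initial(n: int, scene: SceneSpec, rng: np.random.Generator,
                   margin_um: float | None = None):
    """Random sequential placement with a minimum pairwise separation."""
    h_um = scene.image_shape[0] * scene.pixel_size_um
    w_um = scene.image_shape[1] * scene.pixel_size_um
    lo = scene.margin_um if margin_um is None else margin_um
    pts: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(pts) == n:
            break
        x = rng.uniform(lo, w_um - lo)
        y = rng.uniform(lo, h_um - lo)
        if all((x - px) ** 2 + (y - py) ** 2 >= scene.min_separation_um ** 2
               for px, py in pts):
            pts.append((x, y))
    if len(pts) < n:
        raise ValueError("could not place cells at the requested separation")
    return np.array(pts)


def _footprint(radius_px: float, profile: str, ss: int):
    """Unit-peak cell profile patch and its offset, supersampled coverage."""
    r_out = radius_px * (1.6 if profile == "gaussian-blob" else 1.0)
    half = int(np.ceil(r_out)) + 2
    n = 2 * half + 1
    # subpixel coverage via ss x ss oversampling of each pixel
    ax = (np.arange(n * ss) + 0.5) / ss - 0.5 - half
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    rr = np.hypot(yy, xx)
    if profile == "uniform-disk":
        fine = (rr <= radius_px).astype(float)
    else:
        s = radius_px / 2.0
        fine = np.exp(-rr ** 2 / (2 * s ** 2)) * (rr <= r_out)
    patch = fine.reshape(n, ss, n, ss).mean(axis=(1, 3))
    return patch, half


def render_phase_movie(tracks: list[CellTrack], scene: SceneSpec,
                       rng: np.random.Generator | None = None) -> RenderedMovie:
    """Render mass tracks into a phase movie with ground truth.

    Each cell's rendered patch is rescaled so its integrated phase equals
    the scheduled mass exactly (before background noise), hence
    ``compute_cell_mass`` on the ground-truth mask recovers the schedule to
    well within 0.5%.  Overlapping cells are allowed but flagged.
    """
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    n_cells = len(tracks)
    H, W = scene.image_shape
    if n_cells == 0:  # empty scene: one background-only frame
        phase = np.zeros((1, H, W))
        if scene.background_phase_sd > 0:
            phase += rng.normal(0.0, scene.background_phase_sd, size=(1, H, W))
        return RenderedMovie(phase=phase.astype(np.float32),
                             labels=np.zeros((1, H, W), dtype=np.uint16),
                             truth=pd.DataFrame(columns=[
                                 "cell_id", "frame", "x_um", "y_um", "mass_pg",
                                 "radius_um", "subpopulation", "overlaps"]),
                             scene=scene)
    n_frames = max(len(tr) for tr in tracks)
    px = scene.pixel_size_um
    const = MassConstants(wavelength_nm=scene.wavelength_nm,
                          pixel_area_um2=px * px)
    conv = const.pg_per_radian_pixel

    radii = np.clip(rng.normal(scene.cell_radius_um_mean,
                               scene.cell_radius_um_sd, n_cells),
                    scene.cell_radius_um_mean * 0.5, None)
    # placement must keep every cell fully in frame over its whole walk
    margin = max(scene.margin_um,
                 float(radii.max()) + scene.motion_bound_um + 2.0)
    pts = _place_initial(n_cells, scene, rng, margin_um=margin)
    patches = [_footprint(r / px, scene.phase_profile, scene.supersample)
               for r in radii]

    # bounded random walk around each initial position
    pos = np.empty((n_frames, n_cells, 2))
    pos[0] = pts
    for t in range(1, n_frames):
        step = rng.normal(0.0, scene.motion_step_um, size=(n_cells, 2))
        cand = pos[t - 1] + step
        excur = cand - pts
        d = np.linalg.norm(excur, axis=1, keepdims=True)
        over = d[:, 0] > scene.motion_bound_um
        cand[over] = pts[over] + excur[over] / d[over] * scene.motion_bound_um
        pos[t] = cand

    phase = np.zeros((n_frames, H, W), dtype=np.float64)
    labels = np.zeros((n_frames, H, W), dtype=np.uint16)
    rows = []
    for t in range(n_frames):
        claimed = np.zeros((H, W), dtype=bool)
        overlapped: set[int] = set()
        frame_rows = []
        for i, tr in enumerate(tracks):
            if t >= len(tr):
                continue
            mass = tr.masses_pg[t]
            patch, halfp = patches[i]
            cx, cy = pos[t, i]
            r0 = int(round(cy / px)) - halfp
            c0 = int(round(cx / px)) - halfp
            r1, c1 = r0 + patch.shape[0], c0 + patch.shape[1]
            pr0, pc0 = max(0, -r0), max(0, -c0)
            r0, c0 = max(0, r0), max(0, c0)
            r1, c1 = min(H, r1), min(W, c1)
            sub = patch[pr0:pr0 + (r1 - r0), pc0:pc0 + (c1 - c0)]
            total = sub.sum()
            if total <= 0 or mass <= 0:
                continue
            scale = mass / (conv * total)
            phase[t, r0:r1, c0:c1] += scale * sub
            m = sub > 1e-6
            if (claimed[r0:r1, c0:c1] & m).any():
                prev = np.unique(labels[t, r0:r1, c0:c1][claimed[r0:r1, c0:c1] & m])
                overlapped.update(int(p) - 1 for p in prev if p > 0)
                overlapped.add(i)
            labels[t, r0:r1, c0:c1][m] = i + 1
            claimed[r0:r1, c0:c1] |= m
            frame_rows.append({"cell_id": i, "frame": t, "x_um": cx,
                               "y_um": cy, "mass_pg": float(mass),
                               "radius_um": float(radii[i]),
                               "subpopulation": tr.meta.get("subpopulation", ""),
                               "overlaps": False})
        for row in frame_rows:
            if row["cell_id"] in overlapped:
                row["overlaps"] = True
        rows.extend(frame_rows)
        if scene.background_phase_sd > 0:
            phase[t] += rng.normal(0.0, scene.background_phase_sd, size=(H, W))
    truth = pd.DataFrame(rows)
    return RenderedMovie(phase=phase.astype(np.float32), labels=labels,
                         truth=truth, scene=scene)


def render_dpc_intensities(phase_frames: np.ndarray, optics: OpticsSpec,
                           background: float = 1.0,
                           photons: float | None = None,
                           rng: np.random.Generator | None = None
                           ) -> dict[str, np.ndarray]:
    """Forward DPC model: phase stack -> four half-circle intensity stacks.

    Contrast per axis is generated with the same weak-object transfer
    functions used by :func:`mqpi.phase_reconstruction.reconstruct_phase`,
    then unfolded into intensity pairs I = B(1 +/- c).  Optional shot noise
    is Poisson at ``photons`` mean counts per pixel.  Phases above ~1 rad
    violate the linear model; a warning is logged.
    """
    import logging
    phase_frames = np.asarray(phase_frames, dtype=float)
    squeeze = phase_frames.ndim == 2
    if squeeze:
        phase_frames = phase_frames[None]
    if np.abs(phase_frames).max() > 1.0:
        logging.getLogger(__name__).warning(
            "weak-object model: |phase| exceeds 1 rad; linearity degraded")
    shape = phase_frames.shape[1:]
    tfs = transfer_functions(shape, optics)
    out = {k: np.empty_like(phase_frames) for k in
           ("top", "bottom", "left", "right")}
    pair = {"tb": ("top", "bottom"), "lr": ("left", "right")}
    for t in range(phase_frames.shape[0]):
        spec = np.fft.fft2(phase_frames[t])
        for ax in AXES:
            c = np.fft.ifft2(tfs[ax] * spec).real
            a, b = pair[ax]
            out[a][t] = background * (1.0 + c)
            out[b][t] = background * (1.0 - c)
    if photons is not None:
        if rng is None:
            rng = np.random.default_rng()
        for k in out:
            out[k] = rng.poisson(np.clip(out[k], 0, None) * photons) / photons
    if squeeze:
        out = {k: v[0] for k, v in out.items()}
    return out
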