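"""Cell segmentation in phase images and dry-mass computation.

Dry mass follows from the integrated phase shift through the specific
refractive increment alpha (default 1.8e-4 m^3/kg):

    m = lambda / (2 pi alpha) * sum_pixels(phi) * pixel_area

Segmentation is edge-based: Sobel gradient magnitude, threshold (Otsu by
default), dilation to close the edge band, hole filling, a matched erosion
so the mask tracks the true boundary, then small-object removal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology
from scipy import ndimage

from .datatypes import OBS_COLUMNS, PhaseFrame

log = logging.getLogger(__name__)

#: picograms per kilogram / square metres per square micrometre folded in
_PG_PER_KG_UM2 = 1e15 * 1e-12


@dataclass
class MassConstants:
    """Constants converting integrated phase (radians) to dry mass (pg)."""

    alpha_m3_per_kg: float = 1.8e-4
    wavelength_nm: float = 525.0
    pixel_area_um2: float = 0.36

    def __post_init__(self) -> None:
        if min(self.alpha_m3_per_kg, self.wavelength_nm, self.pixel_area_um2) <= 0:
            raise ValueError("all mass constants must be strictly positive")

    @property
    def pg_per_radian_pixel(self) -> float:
        """Mass contribution of one pixel-radian of phase, in pg."""
        lam_m = self.wavelength_nm * 1e-9
        return (lam_m / (2.0 * np.pi * self.alpha_m3_per_kg)
                * self.pixel_area_um2 * _PG_PER_KG_UM2)


@dataclass
class SegmentationParams:
    """Tunable parameters of the edge-based segmentation pipeline."""

    edge_threshold: float | None = None  # None -> Otsu on gradient magnitude
    dilation_radius_px: int = 2
    min_area_px: int = 50
    gaussian_sigma_px: float = 0.0  # optional pre-smoothing


def segment_cells(frame: PhaseFrame | np.ndarray,
                  params: SegmentationParams | None = None) -> np.ndarray:
    """Label image of segmented cells (0 = background)."""
    params = params or SegmentationParams()
    phase = frame.phase if isinstance(frame, PhaseFrame) else np.asarray(frame, float)
    if not np.all(np.isfinite(phase)):
        raise ValueError("phase image contains non-finite values")
    if params.gaussian_sigma_px > 0:
        phase = ndimage.gaussian_filter(phase, params.gaussian_sigma_px)

    grad = filters.sobel(phase)
    if grad.max() == grad.min():
        return np.zeros(phase.shape, dtype=np.int32)
    thr = params.edge_threshold
    if thr is None:
        thr = filters.threshold_otsu(grad)
    edges = grad > thr
    if not edges.any():
        return np.zeros(phase.shape, dtype=np.int32)

    selem = morphology.disk(params.dilation_radius_px)
    mask = morphology.dilation(edges, selem)
    mask = ndimage.binary_fill_holes(mask)
    mask = morphology.erosion(mask, selem)
    # retain objects of at least min_area_px pixels
    mask = morphology.remove_small_objects(mask, max_size=params.min_area_px - 1)
    return measure.label(mask).astype(np.int32)


def compute_cell_mass(frame: PhaseFrame | np.ndarray, mask: np.ndarray,
                      constants: MassConstants | None = None) -> float:
    """Dry mass (pg) of the phase integrated over a boolean mask."""
    constants = constants or MassConstants()
    phase = frame.phase if isinstance(frame, PhaseFrame) else np.asarray(frame, float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != phase.shape:
        raise ValueError("mask must match the frame shape")
    vals = phase[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite phase under mask")
    return float(vals.sum() * constants.pg_per_radian_pixel)


def detect_cells(frame: PhaseFrame, params: SegmentationParams | None = None,
                 constants: MassConstants | None = None,
                 background_correction: bool = True) -> pd.DataFrame:
    """Segment one phase frame and tabulate per-cell observations.

    When ``background_correction`` is on, the median phase of non-cell
    pixels is subtracted before mass integration to remove any DC pedestal.
    Returns a DataFrame with :data:`mqpi.datatypes.OBS_COLUMNS`.
    """
    if constants is None:
        constants = MassConstants(wavelength_nm=frame.wavelength_nm,
                                  pixel_area_um2=frame.pixel_area_um2)
    labels = segment_cells(frame, params)
    phase = frame.phase
    if background_correction and (labels == 0).any():
        phase = phase - np.median(phase[labels == 0])

    px = frame.pixel_size_um
    rows = []
    for rp in measure.regionprops(labels, intensity_image=phase):
        mass = rp.image_intensity[rp.image].sum() * constants.pg_per_radian_pixel
        cy, cx = rp.centroid
        rows.append({
            "frame": frame.frame, "time_h": frame.time_h, "label": rp.label,
            "x_um": cx * px, "y_um": cy * px,
            "area_um2": rp.area * px * px, "mass_pg": float(mass),
            "mean_phase": float(rp.image_intensity[rp.image].mean()),
            "well": frame.well, "position": frame.position,
        })
    if not rows:
        return pd.DataFrame(columns=OBS_COLUMNS)
    return pd.DataFrame(rows)[OBS_COLUMNS]
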