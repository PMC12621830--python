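"""Differential phase contrast (DPC) phase retrieval.

Four brightfield images acquired under complementary half-circle
illuminations (top/bottom, left/right) are combined into two contrast
images.  Under the weak-object approximation each contrast image is a
linear filter of the specimen phase,

    FT[I_dpc](u) = H(u) * FT[phi](u),

with a purely imaginary, antisymmetric phase transfer function H that
depends only on the source geometry and the pupil.  The phase is recovered
by a joint Tikhonov-regularized least-squares inversion over the two
orthogonal axes:

    phi_hat = IFT[ sum_j conj(H_j) FT[I_j] / (sum_j |H_j|^2 + beta) ]

The transfer functions are evaluated numerically on the discrete frequency
grid from the half-circle source and circular pupil, so the same operator
serves as the forward model in :mod:`mqpi.synthetic_data` and as the
inverse here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .datatypes import PhaseFrame

log = logging.getLogger(__name__)

AXES = ("tb", "lr")  # top-bottom split (rows), left-right split (columns)


@dataclass
class OpticsSpec:
    """Imaging-system parameters for the DPC forward/inverse model.

    numerical_aperture : objective NA; the LED half-circles are assumed to
        fill the same NA (matched illumination).
    regularization_beta : Tikhonov parameter added to sum |H|^2.
    """

    numerical_aperture: float = 0.25
    wavelength_nm: float = 525.0
    pixel_size_um: float = 0.6
    regularization_beta: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture < 1:
            raise ValueError("numerical_aperture must lie in (0, 1)")
        if self.regularization_beta <= 0:
            raise ValueError("regularization_beta must be positive")
        if self.wavelength_nm <= 0 or self.pixel_size_um <= 0:
            raise ValueError("wavelength and pixel size must be positive")

    @property
    def cutoff_um(self) -> float:
        """Coherent pupil cutoff frequency NA/lambda in um^-1."""
        return self.numerical_aperture / (self.wavelength_nm * 1e-3)


def _freq_grids(shape: tuple[int, int], pixel_size_um: float):
    fy = np.fft.fftfreq(shape[0], d=pixel_size_um)
    fx = np.fft.fftfreq(shape[1], d=pixel_size_um)
    return np.meshgrid(fy, fx, indexing="ij")


def pupil(shape: tuple[int, int], optics: OpticsSpec) -> np.ndarray:
    """Binary circular pupil on the FFT-layout frequency grid."""
    fy, fx = _freq_grids(shape, optics.pixel_size_um)
    return (np.hypot(fy, fx) <= optics.cutoff_um).astype(float)


def _negate_freq(a: np.ndarray) -> np.ndarray:
    """Map a(u) -> a(-u) on an FFT-layout grid."""
    return np.roll(a[::-1, ::-1], 1, axis=(0, 1))


def phase_transfer_function(shape: tuple[int, int], optics: OpticsSpec,
                            axis: str) -> np.ndarray:
    """Weak-object phase transfer function for one half-circle pair.

    ``axis`` is ``"tb"`` (source split along the row/y frequency axis) or
    ``"lr"`` (split along the column/x axis).  Returns a purely imaginary,
    antisymmetric array in FFT layout, normalized by the DC intensity of
    the full (unsigned) source so that max |H| is O(1).
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    fy, fx = _freq_grids(shape, optics.pixel_size_um)
    P = (np.hypot(fy, fx) <= optics.cutoff_um).astype(float)
    coord = fy if axis == "tb" else fx
    s_signed = P * np.sign(coord)
    dc = P.sum()  # unsigned-source DC intensity, Sum S P^2 with binary masks
    if dc == 0:
        raise ValueError("degenerate optics: empty pupil on this grid")

    # F(u) = sum_{u'} S(u') P(u') P(u'+u); evaluate as a *linear* (zero
    # padded) correlation in DC-centered layout to avoid cyclic aliasing,
    # since the support of F extends to twice the pupil cutoff.
    Pc = np.fft.fftshift(P)
    Sc = np.fft.fftshift(s_signed * P)
    F = signal.correlate(Pc, Sc, mode="same", method="fft")
    F = np.fft.ifftshift(F)
    H = 1j * (F - _negate_freq(F)) / (2.0 * dc)
    return H


def transfer_functions(shape: tuple[int, int],
                       optics: OpticsSpec) -> dict[str, np.ndarray]:
    """Both orthogonal phase transfer functions keyed by axis."""
    return {ax: phase_transfer_function(shape, optics, ax) for ax in AXES}


def dpc_contrast(i_a: np.ndarray, i_b: np.ndarray) -> np.ndarray:
    """Normalized half-circle contrast (i_a - i_b) / (i_a + i_b).

    Pixels where the denominator is non-positive are masked to zero and
    counted in a log warning; for a pure-phase weak object the result is
    zero-mean.
    """
    i_a = np.asarray(i_a, dtype=float)
    i_b = np.asarray(i_b, dtype=float)
    if i_a.shape != i_b.shape:
        raise ValueError("intensity images must share a shape")
    denom = i_a + i_b
    bad = denom <= 0
    out = np.zeros_like(denom)
    np.divide(i_a - i_b, denom, out=out, where=~bad)
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("dpc_contrast: masked %d non-positive-sum pixels", n_bad)
    return out


def reconstruct_phase(contrasts: dict[str, np.ndarray], optics: OpticsSpec,
                      tfs: dict[str, np.ndarray] | None = None,
                      flatten_background: bool = False) -> np.ndarray:
    """Tikhonov inversion of >=2 orthogonal DPC contrast images to phase.

    Joint least-squares over all provided axes; the DC component (absolute
    phase offset, unrecoverable by DPC) is set to zero.  Optional
    ``flatten_background`` removes a best-fit plane afterwards.
    """
    if len(contrasts) < 2:
        raise ValueError("need contrast images for >=2 orthogonal axes")
    shapes = {c.shape for c in contrasts.values()}
    if len(shapes) != 1:
        raise ValueError("contrast images must share a shape")
    shape = shapes.pop()
    if tfs is None:
        tfs = {ax: phase_transfer_function(shape, optics, ax) for ax in contrasts}
    if all(np.abs(tfs[ax]).max() == 0 for ax in contrasts):
        raise ValueError("all transfer functions vanish: degenerate optics")

    num = np.zeros(shape, dtype=complex)
    den = np.full(shape, optics.regularization_beta, dtype=float)
    for ax, c in contrasts.items():
        H = tfs[ax]
        num += np.conj(H) * np.fft.fft2(np.asarray(c, dtype=float))
        den += np.abs(H) ** 2
    phi = np.fft.ifft2(num / den).real
    phi -= phi.mean()
    if flatten_background:
        yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        A = np.column_stack([yy.ravel(), xx.ravel(), np.ones(phi.size)])
        coef, *_ = np.linalg.lstsq(A, phi.ravel(), rcond=None)
        phi = phi - (A @ coef).reshape(shape)
    return phi


def reconstruct_from_intensities(top: np.ndarray, bottom: np.ndarray,
                                 left: np.ndarray, right: np.ndarray,
                                 optics: OpticsSpec, **kw) -> PhaseFrame:
    """Convenience wrapper: four raw half-circle images -> PhaseFrame."""
    contrasts = {"tb": dpc_contrast(top, bottom),
                 "lr": dpc_contrast(left, right)}
    phi = reconstruct_phase(contrasts, optics, **kw)
    return PhaseFrame(phase=phi, pixel_size_um=optics.pixel_size_um,
                      wavelength_nm=optics.wavelength_nm)
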