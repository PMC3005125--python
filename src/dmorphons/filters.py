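"""Loglet quadrature filter banks and local-phase / certainty extraction.

A quadrature filter is a complex directional bandpass filter whose frequency
support is restricted to the half-space in its direction; the argument of
its response is the *local phase* of the image, which encodes the position
within an intensity transition and is invariant to positive intensity
scaling.  The bank is defined in the frequency domain by the polar-separable
function

    H_eta(w) = chi+(eta.w) * (eta.w_hat)^2 * R(||w||),
    R(r)     = exp(-ln^2(r / rho) / ln 2),

with ``chi+`` the indicator of the positive half-space, ``w_hat`` the unit
frequency vector and ``rho`` the center frequency (radians/voxel).  ``R``
peaks at 1 for ``r = rho`` and halves one octave away on either side.

Directions: in 2D the four half-plane-covering orientations at k*pi/4;
in 3D the six non-antipodal vertex directions of a regular icosahedron,
i.e. normalized cyclic permutations of (0, +-1, phi) with phi the golden
ratio (the standard evenly distributed 6-direction quadrature set).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .fields import Volume

__all__ = [
    "QuadratureBank",
    "FilterResponseSet",
    "DephasingSet",
    "directions_2d",
    "directions_3d",
    "radial_profile",
    "frequency_response",
    "make_bank",
    "apply_bank",
    "local_dephasing",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


def directions_2d() -> np.ndarray:
    """The four 2D filter directions (cos(k pi/4), sin(k pi/4)), k=0..3."""
    ang = np.arange(4) * np.pi / 4.0
    return np.stack([np.cos(ang), np.sin(ang)], axis=1)


def directions_3d() -> np.ndarray:
    """Six non-antipodal icosahedron vertex directions, unit-normalized."""
    p = _GOLDEN
    raw = np.array(
        [
            (1.0, p, 0.0),
            (-1.0, p, 0.0),
            (p, 0.0, 1.0),
            (p, 0.0, -1.0),
            (0.0, 1.0, p),
            (0.0, -1.0, p),
        ]
    )
    return raw / np.linalg.norm(raw, axis=1, keepdims=True)


def radial_profile(r, rho: float):
    """Log-normal radial envelope R(r) = exp(-ln^2(r/rho)/ln 2); R(0) = 0."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = np.exp(-np.log(r[pos] / rho) ** 2 / np.log(2.0))
    return out


def frequency_response(eta: np.ndarray, rho: float, shape) -> np.ndarray:
    """Sample H_eta on the DFT frequency grid of an array of given shape."""
    axes = [2.0 * np.pi * np.fft.fftfreq(n) for n in shape]
    omega = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    wnorm = np.linalg.norm(omega, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        what = np.where(wnorm[..., None] > 0, omega / wnorm[..., None], 0.0)
    proj_hat = what @ eta
    proj = omega @ eta
    return (proj > 0) * proj_hat ** 2 * radial_profile(wnorm, rho)


@dataclass
class QuadratureBank:
    """K complex directional kernels with directions ``eta_k`` and center
    frequency ``rho`` (radians/voxel)."""

    directions: np.ndarray  # (K, ndim) unit vectors
    rho: float
    kernel_size: int
    kernels: np.ndarray  # (K,) + (kernel_size,)*ndim, complex

    @property
    def ndim(self) -> int:
        return self.directions.shape[1]

    @property
    def num_filters(self) -> int:
        return self.directions.shape[0]


@dataclass
class FilterResponseSet:
    """Complex responses q(x;k) of a bank, shape (K,) + grid."""

    responses: np.ndarray

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.responses)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.responses)

    @property
    def grid_shape(self) -> tuple:
        return self.responses.shape[1:]


@dataclass
class DephasingSet:
    """Per-filter local phase differences and certainties.

    ``dphi`` lies in (-pi, pi]; ``cert`` is the product of the two response
    amplitudes and is non-negative.
    """

    dphi: np.ndarray
    cert: np.ndarray


def make_bank(rho: float, ndim: int, kernel_size: int = 9) -> QuadratureBank:
    """Build a spatial-domain loglet bank at center frequency ``rho``.

    Each kernel is synthesized by sampling ``H_eta`` on the DFT grid of a
    64-per-axis (2D) / 32-per-axis (3D) array, inverse transforming,
    centering, truncating to ``kernel_size`` per axis, and removing the
    residual DC component of the real part (so constant image regions give
    zero amplitude).
    """
    if not 0 < rho < np.pi:
        raise ValueError("rho must lie in (0, pi) radians/voxel")
    if kernel_size % 2 == 0 or kernel_size < 5:
        raise ValueError("kernel_size must be odd and >= 5")
    if ndim == 2:
        dirs, synth = directions_2d(), 64
    elif ndim == 3:
        dirs, synth = directions_3d(), 32
    else:
        raise ValueError("ndim must be 2 or 3")
    if kernel_size > synth:
        raise ValueError("kernel_size exceeds synthesis grid")
    half = kernel_size // 2
    center = synth // 2
    sl = tuple([slice(center - half, center + half + 1)] * ndim)
    kernels = []
    for eta in dirs:
        H = frequency_response(eta, rho, (synth,) * ndim)
        h = np.fft.fftshift(np.fft.ifftn(H))
        h = h[sl].copy()
        h = h - h.real.mean()  # imaginary part is odd, already zero-mean
        kernels.append(h)
    return QuadratureBank(dirs, float(rho), int(kernel_size), np.stack(kernels))


def apply_bank(v: Volume, bank: QuadratureBank) -> FilterResponseSet:
    """Convolve ``v`` with every kernel (zero padding outside boundaries)."""
    if v.ndim != bank.ndim:
        raise ValueError(f"image is {v.ndim}D but bank is {bank.ndim}D")
    resp = np.stack(
        [fftconvolve(v.data, kern, mode="same") for kern in bank.kernels]
    )
    return FilterResponseSet(resp)


def local_dephasing(rf: FilterResponseSet, rw: FilterResponseSet) -> DephasingSet:
    """Phase differences Delta-phi_k = arg(q_f q_w*) and certainties A_f A_w.

    The dephasing is invariant to positive intensity rescaling of either
    input (arg of a positive real multiple is unchanged), which is what
    makes the phase-based update contrast-invariant.
    """
    if rf.responses.shape != rw.responses.shape:
        raise ValueError("response sets are on different grids or banks")
    prod = rf.responses * np.conj(rw.responses)
    return DephasingSet(dphi=np.angle(prod), cert=np.abs(prod))
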