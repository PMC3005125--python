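"""Per-iteration field computation, accumulation and regularization.

This module houses the three blocks the multiscale driver iterates:

* **Theta** — the update-field computation: either the phase-based Morphons
  update (weighted least squares on per-filter dephasings, with a certainty
  map) or the classical intensity-difference Demons update.
* **Phi** — field accumulation in three flavours: additive, compositive, and
  diffeomorphic (compose with the exponential of the damped update), plus
  the certainty accumulation (ca^2 + cu^2)/(ca + cu).
* **Psi** — certainty-weighted regularization by normalized convolution with
  a Gaussian kernel.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import DisplacementField, Volume, compose_fields, exp_field
from .filters import (
    FilterResponseSet,
    QuadratureBank,
    apply_bank,
    local_dephasing,
)

__all__ = [
    "CertaintyMap",
    "UpdateResult",
    "morphons_update",
    "phase_wls_solve",
    "demons_update",
    "accumulate_certainty",
    "accumulate",
    "normalized_convolution",
    "regularize",
]

ACCUMULATION_MODES = ("additive", "compositive", "diffeomorphic")


@dataclass
class CertaintyMap:
    """Non-negative per-voxel confidence in the displacement estimate."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("certainty must be finite")
        if np.any(self.values < 0):
            raise ValueError("certainty must be non-negative")

    @classmethod
    def zeros(cls, shape) -> "CertaintyMap":
        return cls(np.zeros(shape))


@dataclass
class UpdateResult:
    field: DisplacementField
    certainty: CertaintyMap


def morphons_update(
    f: Volume,
    w: Volume,
    bank: QuadratureBank,
    rf: FilterResponseSet = None,
) -> UpdateResult:
    """Phase-based update field by per-voxel weighted least squares.

    Per voxel, ``d`` minimizes  sum_k [c_k (rho eta_k^T d - dphi_k)]^2, i.e.
    ``d = (N^T C^2 N)^{-1} N^T C^2 Gamma / rho`` with ``N`` stacking the
    filter directions, ``C = diag(c_k)`` and ``Gamma = (dphi_k)``.  Where
    the normal matrix is (numerically) singular, or all certainties vanish,
    ``d`` is set to zero.  The update certainty is ``sum_k c_k``.

    ``rf`` may carry precomputed filter responses of ``f`` (the fixed image
    does not change between iterations of one scale).
    """
    if f.shape != w.shape:
        raise ValueError("fixed and warped images must share a grid")
    if f.ndim != bank.ndim:
        raise ValueError("bank dimensionality does not match images")
    if rf is None:
        rf = apply_bank(f, bank)
    rw = apply_bank(w, bank)
    dp = local_dephasing(rf, rw)
    d = phase_wls_solve(dp.dphi, dp.cert, bank.directions, bank.rho)
    return UpdateResult(DisplacementField(d), CertaintyMap(dp.cert.sum(axis=0)))


def phase_wls_solve(
    dphi: np.ndarray, cert: np.ndarray, directions: np.ndarray, rho: float
) -> np.ndarray:
    """Per-voxel minimizer of  sum_k [c_k (rho eta_k^T d - dphi_k)]^2.

    ``dphi`` and ``cert`` have shape ``(K,) + grid``; ``directions`` is
    ``(K, ndim)``.  Returns displacements with shape ``grid + (ndim,)``;
    zero wherever the normal matrix is numerically singular (smallest
    eigenvalue below 1e-9 of the largest) or every certainty is below
    1e-12 of the global maximum.
    """
    nd = directions.shape[1]
    c2 = cert ** 2
    A = np.einsum("k...,ki,kj->...ij", c2, directions, directions)
    b = np.einsum("k...,ki->...i", c2 * dphi, directions) / rho

    eig = np.linalg.eigvalsh(A)
    lam_min, lam_max = eig[..., 0], eig[..., -1]
    solvable = (lam_max > 0) & (lam_min > 1e-9 * lam_max)
    cmax = cert.max() if cert.size else 0.0
    if cmax > 0:
        solvable &= cert.max(axis=0) > 1e-12 * cmax
    A_safe = np.where(solvable[..., None, None], A, np.eye(nd))
    d = np.linalg.solve(A_safe, b[..., None])[..., 0]
    return np.where(solvable[..., None], d, 0.0)


def demons_update(f: Volume, w: Volume) -> UpdateResult:
    """Classical intensity-difference (SSD) update.

    ``d = (f - w) grad f / (||grad f||^2 + (f - w)^2)``, zero where the
    denominator vanishes; certainty is identically 1 (the Demons baseline
    has no certainty concept).
    """
    if f.shape != w.shape:
        raise ValueError("fixed and warped images must share a grid")
    grads = np.gradient(f.data, edge_order=1)
    if f.ndim == 1:
        grads = [grads]
    g = np.stack(grads, axis=-1)
    diff = f.data - w.data
    denom = np.sum(g ** 2, axis=-1) + diff ** 2
    tiny = 1e-12 * denom.max() if denom.max() > 0 else 0.0
    scale = np.where(denom > tiny, diff / np.where(denom > 0, denom, 1.0), 0.0)
    d = g * scale[..., None]
    return UpdateResult(DisplacementField(d), CertaintyMap(np.ones(f.shape)))


def accumulate_certainty(ca: CertaintyMap, cu: CertaintyMap) -> CertaintyMap:
    """Certainty accumulation (ca^2 + cu^2)/(ca + cu); 0 where ca + cu = 0.

    The output never exceeds max(ca, cu) and is at least their average.
    """
    a, u = ca.values, cu.values
    if a.shape != u.shape:
        raise ValueError("certainty maps must share a grid")
    s = a + u
    out = np.where(s > 0, (a ** 2 + u ** 2) / np.where(s > 0, s, 1.0), 0.0)
    return CertaintyMap(out)


def accumulate(
    Da: DisplacementField,
    Du: DisplacementField,
    ca: CertaintyMap = None,
    cu: CertaintyMap = None,
    mode: str = "diffeomorphic",
    max_step: float = 0.5,
) -> DisplacementField:
    """Accumulate the update ``Du`` into ``Da``.

    The update is damped per voxel by ``wgt = cu/(ca + cu)`` (0 where both
    certainties vanish); passing ``ca = cu = None`` uses undamped weight 1,
    which is the plain Demons behaviour.  Modes:

    * ``additive``       : ``Da + wgt Du``
    * ``compositive``    : ``Da (+) (wgt Du)``
    * ``diffeomorphic``  : ``Da (+) (exp(wgt Du) - Id)``

    With diffeomorphic accumulation every increment is the exponential of a
    velocity field, hence invertible; the composition of invertible steps
    keeps the accumulated deformation free of folding.
    """
    if mode not in ACCUMULATION_MODES:
        raise ValueError(f"unknown accumulation mode {mode!r}")
    if Da.grid_shape != Du.grid_shape:
        raise ValueError("fields must share a grid")
    if (ca is None) != (cu is None):
        raise ValueError("provide both certainties or neither")
    if ca is None:
        damped = Du
    else:
        s = ca.values + cu.values
        wgt = np.where(s > 0, cu.values / np.where(s > 0, s, 1.0), 0.0)
        damped = DisplacementField(Du.vectors * wgt[..., None])
    if mode == "additive":
        return DisplacementField(Da.vectors + damped.vectors)
    if mode == "compositive":
        return compose_fields(Da, damped)
    return compose_fields(Da, exp_field(damped, max_step=max_step))


def _gaussian(arr: np.ndarray, variance: float) -> np.ndarray:
    # zero-padding outside the volume (mode='constant'), truncated at 4 sigma
    return ndimage.gaussian_filter(
        arr, sigma=np.sqrt(variance), mode="constant", cval=0.0, truncate=4.0
    )


def normalized_convolution(
    s: np.ndarray, h: CertaintyMap, variance: float
) -> np.ndarray:
    """Normalized convolution ``s *_h g = ((h s) * g) / (h * g)``.

    ``g`` is a Gaussian kernel of the given variance (voxels^2) with zero
    padding, so certainty outside the volume is implicitly zero.  The output
    is 0 wherever the denominator is below 1e-12 of its maximum, and its
    sup-norm never exceeds that of ``s``.
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    s = np.asarray(s, dtype=float)
    if np.any(h.values < 0):
        raise ValueError("normalization weights must be non-negative")
    if s.shape != h.values.shape:
        raise ValueError("signal and weights must share a grid")
    num = _gaussian(h.values * s, variance)
    den = _gaussian(h.values, variance)
    eps = 1e-12 * den.max() if den.max() > 0 else np.inf
    return np.where(den > eps, num / np.where(den > 0, den, 1.0), 0.0)


def regularize(
    Da: DisplacementField, ca: CertaintyMap, variance: float = 2.0
) -> tuple:
    """Certainty-weighted smoothing of field and certainty.

    Each field component is normalized-convolved with normalization ``ca``,
    then the certainty itself is regularized the same way (``ca *_ca g``),
    preserving the correspondence between vectors and their confidence.
    Displacement propagates from high-certainty areas into low-certainty
    ones, and component amplitudes never increase.
    """
    if Da.grid_shape != ca.values.shape:
        raise ValueError("field and certainty must share a grid")
    out = np.empty_like(Da.vectors)
    for i in range(Da.ndim):
        out[..., i] = normalized_convolution(Da.vectors[..., i], ca, variance)
    ca_out = CertaintyMap(
        np.maximum(normalized_convolution(ca.values, ca, variance), 0.0)
    )
    return DisplacementField(out), ca_out
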