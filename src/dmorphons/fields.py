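"""Dense displacement-field algebra: warping, composition, exponentiation.

A deformable registration manipulates three kinds of objects: scalar images
(:class:`Volume`), per-voxel displacement vector fields
(:class:`DisplacementField`), and per-voxel Jacobian determinants of the
associated deformation (:class:`JacobianMap`).

Conventions
-----------
* A displacement field ``D`` is stored in **voxel units** on the grid of the
  fixed image; the deformation it induces is ``Delta(x) = x + D(x)``.
  Physical spacing is metadata used only when reporting distances in mm.
* All float resampling is linear interpolation; sample coordinates falling
  outside the grid are clamped to the nearest in-grid point.
* The warp of a vector field and the compositive accumulation ``D1 (+) D2``
  satisfy ``D1 (+) D2 = D2 + (D1 warped by D2)``, whose deformation is the
  function composition ``Delta1 o Delta2``.
* The exponential of a (stationary) velocity field is the time-1 flow of
  ``du/dt = D(u)``, computed by scaling and squaring: halve the field until
  its sup-norm is below ``max_step`` (0.5 voxels by default), take the
  first-order step, then square (self-compose) back up.  The result is a
  diffeomorphism for smooth ``D``.
"""
from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "DisplacementField",
    "JacobianMap",
    "warp_volume",
    "warp_field",
    "compose_fields",
    "exp_field",
    "jacobian_determinant",
]


@dataclass
class Volume:
    """Scalar image on a regular voxel grid.

    Parameters
    ----------
    data:
        Real-valued array, 2D or 3D, finite everywhere.
    spacing:
        Physical voxel size per axis in mm; defaults to isotropic 1 mm.
    """

    data: np.ndarray
    spacing: tuple = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"Volume must be 2D or 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data must be finite")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError("spacing length must match ndim")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing)


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors in voxel units, component axis last.

    ``vectors`` has shape ``grid_shape + (ndim,)``; component ``i`` displaces
    along array axis ``i``.
    """

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        nd = self.vectors.shape[-1]
        if self.vectors.ndim != nd + 1 or nd not in (2, 3):
            raise ValueError(
                f"vectors must have shape grid+(ndim,), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement components must be finite")

    @classmethod
    def zeros(cls, grid_shape) -> "DisplacementField":
        grid_shape = tuple(grid_shape)
        return cls(np.zeros(grid_shape + (len(grid_shape),)))

    @property
    def ndim(self) -> int:
        return self.vectors.shape[-1]

    @property
    def grid_shape(self) -> tuple:
        return self.vectors.shape[:-1]

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean norm of the displacement."""
        return np.sqrt(np.sum(self.vectors ** 2, axis=-1))

    def max_norm(self) -> float:
        """Sup-norm ``max_x ||D(x)||`` in voxels."""
        return float(self.magnitude().max())

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.vectors.copy())


@dataclass
class JacobianMap:
    """Per-voxel determinant of the deformation Jacobian (volume ratio)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Jacobian values must be finite")

    def min(self) -> float:
        return float(self.values.min())

    def max(self) -> float:
        return float(self.values.max())


def _identity_coords(grid_shape) -> np.ndarray:
    """Stacked voxel-index coordinates, shape (ndim,) + grid_shape."""
    return np.indices(grid_shape, dtype=float)


def _resample(arr: np.ndarray, coords: np.ndarray) -> np.ndarray:
    # order=1 linear interpolation; mode='nearest' clamps out-of-grid sample
    # coordinates to the boundary (equivalent to truncating the coordinate).
    return ndimage.map_coordinates(arr, coords, order=1, mode="nearest")


def _check_same_grid(a_shape, b_shape, what: str):
    if tuple(a_shape) != tuple(b_shape):
        raise ValueError(f"{what}: grid shapes differ, {a_shape} vs {b_shape}")


def warp_volume(m: Volume, D: DisplacementField) -> Volume:
    """Warp image ``m`` by ``D``: ``output(x) = m(x + D(x))``.

    Linear interpolation; coordinates outside the grid of ``m`` are clamped
    to the closest in-grid point.  With ``D = 0`` the output is bit-exact.
    """
    if m.ndim != D.ndim:
        raise ValueError(f"ndim mismatch: image {m.ndim}D vs field {D.ndim}D")
    _check_same_grid(m.shape, D.grid_shape, "warp_volume")
    coords = _identity_coords(D.grid_shape) + np.moveaxis(D.vectors, -1, 0)
    return Volume(_resample(m.data, coords), m.spacing)


def warp_field(D1: DisplacementField, D2: DisplacementField) -> DisplacementField:
    """Resample each component of ``D1`` at ``x + D2(x)`` (``D1 <> D2``)."""
    _check_same_grid(D1.grid_shape, D2.grid_shape, "warp_field")
    coords = _identity_coords(D2.grid_shape) + np.moveaxis(D2.vectors, -1, 0)
    out = np.empty_like(D1.vectors)
    for i in range(D1.ndim):
        out[..., i] = _resample(D1.vectors[..., i], coords)
    return DisplacementField(out)


def compose_fields(D1: DisplacementField, D2: DisplacementField) -> DisplacementField:
    """Compositive accumulation ``D1 (+) D2 = D2 + D1 <> D2``.

    The deformation of the result is ``Delta1 o Delta2``; translations
    therefore compose additively and the zero field is neutral.
    """
    _check_same_grid(D1.grid_shape, D2.grid_shape, "compose_fields")
    return DisplacementField(D2.vectors + warp_field(D1, D2).vectors)


def exp_field(D: DisplacementField, max_step: float = 0.5) -> DisplacementField:
    """Exponential of a velocity field by scaling and squaring.

    Returns ``E`` with ``Id + E ~= exp(D)``, the time-1 flow of
    ``du/dt = D(u)``.  The scaling exponent ``k`` is the smallest
    non-negative integer with ``||2^-k D||_inf < max_step`` (0.5 voxels by
    default); the scaled field is then self-composed ``k`` times.  ``k = 0``
    reduces to the first-order approximation ``E = D``.
    """
    if max_step <= 0:
        raise ValueError("max_step must be positive")
    mx = D.max_norm()
    k = 0
    while mx / (2 ** k) >= max_step and k < 60:
        k += 1
    E = DisplacementField(D.vectors / (2 ** k))
    for _ in range(k):
        E = compose_fields(E, E)
    return E


def jacobian_determinant(D: DisplacementField) -> JacobianMap:
    """Determinant of ``J_ij = delta_ij + d d_i / d x_j`` per voxel.

    Centered finite differences in the interior, one-sided first differences
    at boundary voxels.
    """
    nd = D.ndim
    if any(s < 3 for s in D.grid_shape):
        raise ValueError("grid must be at least 3 voxels per axis")
    J = np.zeros(D.grid_shape + (nd, nd))
    for i in range(nd):
        grads = np.gradient(D.vectors[..., i], edge_order=1)
        if nd == 1:
            grads = [grads]
        for j in range(nd):
            J[..., i, j] = grads[j]
        J[..., i, i] += 1.0
    return JacobianMap(np.linalg.det(J))
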