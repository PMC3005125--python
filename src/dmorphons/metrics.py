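"""Evaluation quantities: SSD, harmonic energy, Jacobian counts, landmark
errors, mask volume change and mutual information."""
from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
from scipy import ndimage

from .fields import DisplacementField, Volume, jacobian_determinant, warp_volume

__all__ = [
    "LandmarkSet",
    "MetricReport",
    "ssd",
    "harmonic_energy",
    "count_inverted",
    "landmark_error",
    "mask_volume_change",
    "mutual_information",
]


@dataclass
class LandmarkSet:
    """Point positions in 0-based voxel coordinates of a named grid."""

    points: np.ndarray  # (n_points, ndim)
    label: str = ""

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    @classmethod
    def from_file(cls, path, label: str = "") -> "LandmarkSet":
        """Whitespace-delimited text, one point per line, voxel coordinates."""
        return cls(np.loadtxt(path, ndmin=2), label=label)

    def validate_bounds(self, grid_shape):
        hi = np.asarray(grid_shape, dtype=float) - 1
        if np.any(self.points < 0) or np.any(self.points > hi):
            raise ValueError("landmarks fall outside the grid")


@dataclass
class MetricReport:
    ssd: float
    harmonic_energy: float
    min_jacobian: float
    n_inverted_voxels: int
    landmark_errors: np.ndarray = None  # per point, mm
    volume_change_pct: float = None

    def as_dict(self) -> dict:
        out = {
            "ssd": self.ssd,
            "harmonic_energy": self.harmonic_energy,
            "min_jacobian": self.min_jacobian,
            "n_inverted_voxels": self.n_inverted_voxels,
        }
        if self.landmark_errors is not None:
            le = np.asarray(self.landmark_errors, dtype=float)
            out["landmark_error_mean_mm"] = float(le.mean())
            out["landmark_error_std_mm"] = float(le.std())
            out["landmark_error_max_mm"] = float(le.max())
        if self.volume_change_pct is not None:
            out["volume_change_pct"] = float(self.volume_change_pct)
        return out


def ssd(f: Volume, m: Volume, D: DisplacementField = None) -> float:
    """Sum of squared differences between ``f`` and ``m`` warped by ``D``."""
    if f.shape != m.shape:
        raise ValueError("images must share a grid")
    w = m if D is None else warp_volume(m, D)
    return float(np.sum((f.data - w.data) ** 2))


def harmonic_energy(D: DisplacementField) -> float:
    """Half the summed squared gradient norms of all field components.

    Centered differences in the interior; invariant under adding a constant
    displacement.
    """
    if any(s < 3 for s in D.grid_shape):
        raise ValueError("grid must be at least 3 voxels per axis")
    total = 0.0
    for i in range(D.ndim):
        for g in np.gradient(D.vectors[..., i], edge_order=1):
            total += float(np.sum(g ** 2))
    return 0.5 * total


def count_inverted(D: DisplacementField) -> int:
    """Number of voxels with negative deformation Jacobian determinant."""
    return int(np.sum(jacobian_determinant(D).values < 0))


def landmark_error(
    L_f: LandmarkSet,
    L_m: LandmarkSet,
    D: DisplacementField,
    spacing=None,
) -> np.ndarray:
    """Per-point Euclidean error in mm of ``p_m - (p_f + D(p_f))``.

    ``D`` is sampled at the (possibly non-integer) fixed-image landmark
    positions by linear interpolation; the voxel-space residual is then
    scaled by the physical spacing.
    """
    if L_f.points.shape != L_m.points.shape:
        raise ValueError("landmark sets must be paired (same count and ndim)")
    nd = D.ndim
    if L_f.points.shape[1] != nd:
        raise ValueError("landmark dimensionality does not match the field")
    spacing = np.ones(nd) if spacing is None else np.asarray(spacing, dtype=float)
    coords = L_f.points.T  # (nd, n_points)
    disp = np.stack(
        [
            ndimage.map_coordinates(D.vectors[..., i], coords, order=1, mode="nearest")
            for i in range(nd)
        ],
        axis=1,
    )
    residual = (L_m.points - (L_f.points + disp)) * spacing
    return np.linalg.norm(residual, axis=1)


def mask_volume_change(mask: Volume, D: DisplacementField) -> float:
    """Percent volume change of a binary mask under warping.

    ``100 (V_warped - V_orig)/V_orig`` where V counts nonzero voxels of the
    nearest-neighbour-warped mask.
    """
    vals = np.unique(mask.data)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("mask must be binary (0/1)")
    v_orig = float(np.count_nonzero(mask.data))
    if v_orig == 0:
        raise ValueError("mask is empty")
    coords = np.indices(D.grid_shape, dtype=float) + np.moveaxis(D.vectors, -1, 0)
    warped = ndimage.map_coordinates(mask.data, coords, order=0, mode="nearest")
    v_warp = float(np.count_nonzero(warped))
    return 100.0 * (v_warp - v_orig) / v_orig


def mutual_information(f: Volume, w: Volume, bins: int = 64) -> float:
    """Joint-histogram mutual information in bits.

    Equal-width bins over each image's observed range; only intended for
    reporting, never as an optimization objective.
    """
    if f.shape != w.shape:
        raise ValueError("images must share a grid")
    hist, _, _ = np.histogram2d(f.data.ravel(), w.data.ravel(), bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))
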