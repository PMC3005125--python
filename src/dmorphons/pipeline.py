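"""Multiscale nonparametric registration driver.

The driver runs the classical coarse-to-fine loop shared by Demons and
Morphons: at each scale j = J..0 the images are smoothed and decimated by
kappa^j, and the three blocks are iterated —

    warp:          w  = m_j o Delta_a
    update:        Du <- Theta(f_j, w)
    accumulate:    Da <- Phi(Da, Du)          (additive / compositive / diffeo)
    regularize:    Da <- Psi(Da)

— until the relative SSD change drops below a tolerance (with a minimum and
maximum iteration count), after which the field (and, for Morphons, the
accumulated certainty) is linearly upsampled to the next finer grid with
vector magnitudes rescaled by kappa.

Fields live in voxel units of the current scale's grid; a single quadrature
bank at fixed rho is used at every scale, which probes a one-octave-higher
image frequency each time the grid coarsens.
"""
from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
from scipy import ndimage

from .fields import (
    DisplacementField,
    Volume,
    jacobian_determinant,
    warp_volume,
)
from .filters import make_bank, apply_bank
from .metrics import harmonic_energy, ssd
from .updates import (
    ACCUMULATION_MODES,
    CertaintyMap,
    accumulate,
    accumulate_certainty,
    demons_update,
    morphons_update,
    regularize,
)

__all__ = [
    "RegistrationConfig",
    "IterationRecord",
    "RegistrationResult",
    "downsample",
    "upsample_field",
    "register",
]


@dataclass
class RegistrationConfig:
    """Parameters of the multiscale driver.

    ``num_scales`` is the coarsest scale index J (J+1 grids are visited; it
    is auto-capped so the coarsest grid still spans twice the filter kernel
    per axis).  ``sigma_psi_sq`` is the *variance* of the regularization
    Gaussian in voxels^2.  The stopping rule at each scale is: at least
    ``min_iters`` updates, at most ``max_iters``, stopping early once the
    relative SSD change falls below ``ssd_rel_tol`` (0.01% by default).
    """

    method: str = "morphons"
    accumulation: str = "diffeomorphic"
    num_scales: int = 3
    subsample: int = 2
    sigma_psi_sq: float = 2.0
    min_iters: int = 10
    max_iters: int = 20
    ssd_rel_tol: float = 1e-4
    rho: float = np.pi / 2
    kernel_size: int = 9
    max_step: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("morphons", "demons"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.accumulation not in ACCUMULATION_MODES:
            raise ValueError(f"unknown accumulation {self.accumulation!r}")
        if self.num_scales < 0:
            raise ValueError("num_scales must be >= 0")
        if self.subsample < 2:
            raise ValueError("subsample factor must be >= 2")
        if not 0 < self.min_iters <= self.max_iters:
            raise ValueError("need 0 < min_iters <= max_iters")
        if self.ssd_rel_tol <= 0 or self.sigma_psi_sq <= 0 or self.max_step <= 0:
            raise ValueError("tolerances and variances must be positive")


@dataclass
class IterationRecord:
    scale: int
    iteration: int
    ssd: float
    harmonic_energy: float
    min_jacobian: float


@dataclass
class RegistrationResult:
    field: DisplacementField
    certainty: CertaintyMap
    log: list = _dc_field(default_factory=list)

    def log_rows(self):
        """Log as a list of plain dicts (for CSV/DataFrame export)."""
        return [vars(r).copy() for r in self.log]


def downsample(v: Volume, j: int, kappa: int = 2) -> Volume:
    """Antialias-smooth (Gaussian, sigma = kappa^j / 2) and decimate by kappa^j."""
    if j < 0:
        raise ValueError("scale index must be >= 0")
    if j == 0:
        return v.copy()
    step = kappa ** j
    # 'nearest' edge handling so constant images stay constant at every scale
    smoothed = ndimage.gaussian_filter(v.data, sigma=step / 2.0, mode="nearest")
    sl = tuple([slice(None, None, step)] * v.ndim)
    out = smoothed[sl]
    if any(s < 3 for s in out.shape):
        raise ValueError("downsampled grid smaller than kernel support")
    return Volume(out, tuple(s * step for s in v.spacing))


def _upsample_scalar(arr: np.ndarray, kappa: int, target_shape) -> np.ndarray:
    """Linear interpolation of a coarse-grid scalar onto the kappa-finer grid."""
    coords = np.indices(target_shape, dtype=float) / kappa
    return ndimage.map_coordinates(arr, coords, order=1, mode="nearest")


def upsample_field(
    D: DisplacementField, kappa: int = 2, target_shape=None
) -> DisplacementField:
    """Transfer a field to the kappa-times finer grid.

    Each component is linearly interpolated onto the finer grid and the
    vector magnitudes are multiplied by kappa (fields are stored in voxel
    units, so the same physical displacement spans kappa-times more voxels
    on the finer grid).
    """
    if kappa < 2:
        raise ValueError("kappa must be >= 2")
    if target_shape is None:
        target_shape = tuple(s * kappa for s in D.grid_shape)
    out = np.empty(tuple(target_shape) + (D.ndim,))
    for i in range(D.ndim):
        out[..., i] = kappa * _upsample_scalar(D.vectors[..., i], kappa, target_shape)
    return DisplacementField(out)


def _cap_scales(shape, J: int, kappa: int, kernel_size: int) -> int:
    """Largest usable J so the coarsest grid spans >= 2 kernel widths."""
    j = 0
    while j < J:
        nxt = [int(np.ceil(s / kappa ** (j + 1))) for s in shape]
        if min(nxt) < 2 * kernel_size:
            break
        j += 1
    return j


def register(f: Volume, m: Volume, cfg: RegistrationConfig) -> RegistrationResult:
    """Estimate ``Da`` such that ``m o Delta_a ~= f``.

    Deterministic given its inputs (no randomness in the algorithm).
    Returns the finest-scale field, the accumulated certainty and a
    per-scale, per-iteration metric log (SSD, harmonic energy, min
    Jacobian).
    """
    if f.ndim != m.ndim or f.shape != m.shape:
        raise ValueError("fixed and moving images must share shape (resample first)")
    if f.data.size == 0:
        raise ValueError("empty grid")

    kappa = cfg.subsample
    J = _cap_scales(f.shape, cfg.num_scales, kappa, cfg.kernel_size)
    bank = (
        make_bank(cfg.rho, f.ndim, cfg.kernel_size)
        if cfg.method == "morphons"
        else None
    )

    Da = None
    ca = None
    log = []
    for j in range(J, -1, -1):
        fj = downsample(f, j, kappa)
        mj = downsample(m, j, kappa)
        if Da is None:
            Da = DisplacementField.zeros(fj.shape)
            ca = CertaintyMap.zeros(fj.shape)
        else:
            Da = upsample_field(Da, kappa, fj.shape)
            ca = CertaintyMap(
                np.maximum(_upsample_scalar(ca.values, kappa, fj.shape), 0.0)
            )
        rf = apply_bank(fj, bank) if bank is not None else None

        prev_ssd = None
        for it in range(1, cfg.max_iters + 1):
            w = warp_volume(mj, Da)
            cur_ssd = ssd(fj, w)
            if (
                prev_ssd is not None
                and it > cfg.min_iters
                and prev_ssd > 0
                and abs(cur_ssd - prev_ssd) / prev_ssd < cfg.ssd_rel_tol
            ):
                break
            if cfg.method == "morphons":
                upd = morphons_update(fj, w, bank, rf=rf)
                Da = accumulate(
                    Da, upd.field, ca, upd.certainty,
                    mode=cfg.accumulation, max_step=cfg.max_step,
                )
                ca = accumulate_certainty(ca, upd.certainty)
                Da, ca = regularize(Da, ca, cfg.sigma_psi_sq)
            else:
                upd = demons_update(fj, w)
                Da = accumulate(
                    Da, upd.field, mode=cfg.accumulation, max_step=cfg.max_step
                )
                Da, _ = regularize(
                    Da, CertaintyMap(np.ones(fj.shape)), cfg.sigma_psi_sq
                )
            log.append(
                IterationRecord(
                    scale=j,
                    iteration=it,
                    ssd=cur_ssd,
                    harmonic_energy=harmonic_energy(Da),
                    min_jacobian=jacobian_determinant(Da).min(),
                )
            )
            prev_ssd = cur_ssd

    return RegistrationResult(field=Da, certainty=ca, log=log)
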