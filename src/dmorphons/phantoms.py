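"""Synthetic phantoms with known ground truth.

Three families make the registration methods testable without any data
download:

* a blurred disk and its intensity-rescaled copy (multiplication by 0.75) —
  identical shape, different contrast; a phase-based method should return a
  (near) zero field here while an intensity-based one deforms the rim;
* a disk with a bright central hole versus a plain disk — a structure
  missing in the moving image, which drives additive accumulation into
  folding (negative Jacobians) while diffeomorphic accumulation compresses
  the hole towards a near-singular but invertible point;
* a band-limited random texture warped by a known smooth diffeomorphism —
  a parameter-recovery fixture with a ground-truth field.

All generators are deterministic functions of their spec (including the
seed); ground-truth deformations are exponentials of smooth velocity
fields, hence invertible by construction (asserted).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import DisplacementField, Volume, exp_field, jacobian_determinant, warp_volume

__all__ = [
    "PhantomSpec",
    "random_velocity_field",
    "make_scaled_disk_pair",
    "make_hole_disk_pair",
    "make_ground_truth_diffeo",
    "make_textured_pair",
]


@dataclass
class PhantomSpec:
    """Parameters of the phantom generators.

    Defaults: 2D 128^2 grid, disk radius r1 = 30 with hole/annulus margin
    r2 = 10, blur sigma 2 voxels (the disk rim then spans several filter
    wavelengths at rho = pi/2), intensity scale 0.75, and smooth random
    deformations of 4-voxel amplitude and 8-voxel correlation length.
    ``contrast_scale`` optionally rescales moving-image intensities inside
    the embedded blob of the textured phantom (contrast-enhancement
    emulation); 1 disables it.
    """

    kind: str = "scaled_disk_pair"
    size: int = 128
    r1: float = 30.0
    r2: float = 10.0
    blur_sigma: float = 2.0
    intensity_scale: float = 0.75
    texture_seed: int = 0
    deform_amplitude: float = 4.0
    deform_smoothness: float = 12.0
    contrast_scale: float = 1.0
    ndim: int = 2

    def __post_init__(self):
        if self.kind not in ("scaled_disk_pair", "hole_disk_pair", "textured_pair"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.r1 <= 0 or self.r2 < 0:
            raise ValueError("radii must be positive")
        if self.r1 + self.r2 >= self.size / 2:
            raise ValueError("disk must fit inside the frame (r1 + r2 < size/2)")
        if self.deform_amplitude < 0:
            raise ValueError("deform_amplitude must be >= 0")
        if self.ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")

    @property
    def shape(self) -> tuple:
        return (self.size,) * self.ndim


def _radius_grid(spec: PhantomSpec) -> np.ndarray:
    center = (spec.size - 1) / 2.0
    coords = np.indices(spec.shape, dtype=float) - center
    return np.sqrt(np.sum(coords ** 2, axis=0))


def _blur(arr: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return arr
    return ndimage.gaussian_filter(arr, sigma=sigma, mode="constant")


def make_scaled_disk_pair(spec: PhantomSpec):
    """Blurred disk and its 0.75x intensity-rescaled copy.

    Returns ``(fixed, moving, contour)`` where moving is elementwise
    ``intensity_scale * fixed`` and ``contour`` are points on the disk rim
    (for overlay plots).
    """
    if spec.kind != "scaled_disk_pair":
        raise ValueError("spec.kind must be 'scaled_disk_pair'")
    r = _radius_grid(spec)
    fixed = Volume(_blur((r <= spec.r1).astype(float), spec.blur_sigma))
    moving = Volume(spec.intensity_scale * fixed.data)
    center = (spec.size - 1) / 2.0
    ang = np.linspace(0, 2 * np.pi, 128, endpoint=False)
    if spec.ndim == 2:
        contour = np.stack(
            [center + spec.r1 * np.cos(ang), center + spec.r1 * np.sin(ang)], axis=1
        )
    else:
        contour = np.stack(
            [
                center + spec.r1 * np.cos(ang),
                center + spec.r1 * np.sin(ang),
                np.full_like(ang, center),
            ],
            axis=1,
        )
    return fixed, moving, contour


def make_hole_disk_pair(spec: PhantomSpec):
    """Disk of radius r1 + r2 with a bright central hole vs a disk of r1.

    Fixed: indicator of the large disk plus the indicator of the central
    hole (annulus at 0.5, bright center at 1 after normalization), blurred.
    Moving: disk of radius r1 at the annulus intensity, blurred.  Both use
    the same intensity scaling; the hole structure is simply absent from
    the moving image.
    """
    if spec.kind != "hole_disk_pair":
        raise ValueError("spec.kind must be 'hole_disk_pair'")
    r = _radius_grid(spec)
    fixed_raw = (r <= spec.r1 + spec.r2).astype(float) + (r <= spec.r2).astype(float)
    fixed = Volume(_blur(fixed_raw / 2.0, spec.blur_sigma))
    moving = Volume(_blur((r <= spec.r1).astype(float) / 2.0, spec.blur_sigma))
    return fixed, moving


def _boundary_window(shape, width: float) -> np.ndarray:
    """Separable smooth taper: 0 at the boundary, 1 beyond ``width`` voxels."""
    win = np.ones(shape)
    for ax, n in enumerate(shape):
        d = np.minimum(np.arange(n), np.arange(n)[::-1]) / max(width, 1e-9)
        t = np.clip(d, 0.0, 1.0)
        ramp = t * t * (3.0 - 2.0 * t)  # smoothstep
        sl = [None] * len(shape)
        sl[ax] = slice(None)
        win = win * ramp[tuple(sl)]
    return win


def random_velocity_field(
    shape,
    amplitude: float,
    smoothness: float,
    rng: np.random.Generator,
    taper: float = None,
) -> DisplacementField:
    """Gaussian-smoothed white-noise vector field with sup-norm ``amplitude``.

    The field is tapered to zero within ``taper`` voxels of the boundary
    (default: the smoothness length) so that the flow it generates is a
    diffeomorphism of the image domain itself — trajectories never leave
    the grid, which would otherwise couple the deformation to the
    boundary-clamping convention of the interpolator.
    """
    shape = tuple(shape)
    nd = len(shape)
    if taper is None:
        taper = smoothness
    v = rng.standard_normal(shape + (nd,))
    win = _boundary_window(shape, taper)
    for i in range(nd):
        v[..., i] = win * ndimage.gaussian_filter(
            v[..., i], sigma=smoothness, mode="nearest"
        )
    mx = np.sqrt(np.sum(v ** 2, axis=-1)).max()
    if mx > 0 and amplitude > 0:
        v *= amplitude / mx
    else:
        v[:] = 0.0
    return DisplacementField(v)


def make_ground_truth_diffeo(spec: PhantomSpec) -> DisplacementField:
    """A known smooth diffeomorphic displacement: exp of a random velocity.

    The velocity field is smoothed white noise (correlation length
    ``deform_smoothness``) rescaled to sup-norm ``deform_amplitude``; its
    exponential has positive Jacobian by construction, which is asserted.
    """
    rng = np.random.default_rng(spec.texture_seed)
    V = random_velocity_field(
        spec.shape, spec.deform_amplitude, spec.deform_smoothness, rng
    )
    E = exp_field(V)
    if spec.deform_amplitude > 0:
        assert jacobian_determinant(E).min() > 0, "generated field is not invertible"
    return E


def make_textured_pair(spec: PhantomSpec):
    """Band-limited random texture warped by a known diffeomorphism.

    Returns ``(fixed, moving, truth)``.  ``truth = exp(V)`` is the field a
    registration of ``moving`` onto ``fixed`` should recover: the moving
    image is the fixed texture warped by ``exp(-V)``, so that
    ``moving o Delta_truth ~= fixed``.  If ``contrast_scale != 1`` the
    moving intensities are additionally rescaled inside the embedded blob,
    emulating a local contrast-enhancement difference.

    Two synthesis choices keep the ground truth clean: the texture fades to
    a uniform border band (as anatomy fades to air at the edge of a scan),
    so border voxels carry no spurious structure for the filters, and the
    moving image is resampled with cubic splines — the generator emulates a
    continuous underlying scene, so its own sampling must be more accurate
    than the linear interpolation of the registration under test.
    """
    if spec.kind != "textured_pair":
        raise ValueError("spec.kind must be 'textured_pair'")
    rng = np.random.default_rng(spec.texture_seed)
    noise = ndimage.gaussian_filter(
        rng.standard_normal(spec.shape), sigma=1.5, mode="nearest"
    )
    noise -= noise.min()
    if noise.max() > 0:
        noise /= noise.max()
    r = _radius_grid(spec)
    blob = np.exp(-(r ** 2) / (2 * (spec.size / 6.0) ** 2))
    img = np.clip(0.7 * noise + 0.3 * blob, 0.0, 1.0)
    fixed = Volume(img * _boundary_window(spec.shape, 16.0))

    V = random_velocity_field(
        spec.shape, spec.deform_amplitude, spec.deform_smoothness, rng
    )
    truth = exp_field(V)
    inverse = exp_field(DisplacementField(-V.vectors))
    coords = np.indices(spec.shape, dtype=float) + np.moveaxis(
        inverse.vectors, -1, 0
    )
    moving = Volume(
        ndimage.map_coordinates(fixed.data, coords, order=3, mode="nearest")
    )
    if spec.contrast_scale != 1.0:
        region = blob > 0.5
        data = moving.data.copy()
        data[region] *= spec.contrast_scale
        moving = Volume(data)
    if spec.deform_amplitude > 0:
        assert jacobian_determinant(truth).min() > 0
    return fixed, moving, truth
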