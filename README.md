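# dmorphons

Deformable (nonparametric) image registration for 2D/3D scalar volumes,
with **phase-based Morphons** and **intensity-based Demons** updates and an
optional **diffeomorphic accumulation** step that keeps the estimated
deformation invertible.

## Why

Nonparametric registration estimates a per-voxel displacement field D such
that the warped moving image matches the fixed image, m∘(Id + D) ≈ f.
Intensity-driven methods (Demons) fail when the same tissue has different
intensities in the two images — e.g. CT with and without iodine contrast —
because they try to equalize intensities by deforming geometry. The
Morphons update instead matches **local phase** from complex quadrature
(loglet) filters: per filter direction η_k at center frequency ρ, the
dephasing Δϕ_k = arg(q_f q_w*) estimates ρ η_kᵀd of the local displacement,
and a per-voxel weighted least squares

d(x) = argmin_d Σ_k [c_k(x) (ρ η_kᵀ d − Δϕ_k(x))]²,  c_k = A_f A_w,

turns the K dephasings into a displacement, weighted by the filter
amplitudes (certainty). Local phase is invariant to positive intensity
scaling, so contrast differences produce no spurious deformation.

Displacement fields accumulate compositively, D_a ⊕ D_u = D_u + D_a ⋄ D_u,
and in the diffeomorphic variants each (certainty-damped) update is first
exponentiated — exp(D_u) computed by scaling and squaring — so the
accumulated deformation is a composition of flows and its Jacobian
determinant stays positive. Regularization is certainty-weighted
normalized convolution, and the whole loop runs coarse-to-fine in a
multiscale pyramid. See `docs/methods.md` for the full model.

## Worked example

Registering a blurred disk against the same disk with intensities
multiplied by 0.75 — same shape, different contrast:

```python
import numpy as np
from dmorphons import (PhantomSpec, make_scaled_disk_pair,
                       RegistrationConfig, register)

fixed, moving, _ = make_scaled_disk_pair(PhantomSpec(kind="scaled_disk_pair"))

for method in ("morphons", "demons"):
    cfg = RegistrationConfig(method=method, accumulation="diffeomorphic")
    res = register(fixed, moving, cfg)
    mag = res.field.magnitude()
    print(f"{method:9s} mean |D| = {mag.mean():.2e}  max |D| = {mag.max():.2f} voxels")
```

```
morphons  mean |D| = 9.11e-16  max |D| = 0.00 voxels
demons    mean |D| = 4.57e-01  max |D| = 3.30 voxels
```

The phase-based method correctly reports "no deformation" while the
intensity-based method invents a 3-voxel rim deformation to compensate for
the contrast difference.

The invertibility contrast on the missing-structure phantom (a disk
registered onto a disk with a bright central hole, probed with a filter
wavelength comparable to the structure gap):

```python
from dmorphons import make_hole_disk_pair, jacobian_determinant

fixed, moving = make_hole_disk_pair(PhantomSpec(kind="hole_disk_pair"))
for mode in ("additive", "diffeomorphic"):
    cfg = RegistrationConfig(method="morphons", accumulation=mode,
                             rho=np.pi / 8, kernel_size=25)
    res = register(fixed, moving, cfg)
    print(f"{mode:13s} min Jacobian = {jacobian_determinant(res.field).min():+.3f}")
```

```
additive      min Jacobian = -0.160
diffeomorphic min Jacobian = +0.061
```

Additive accumulation folds the field (negative Jacobian: voxels inverted,
non-physical), while diffeomorphic accumulation compresses the unmatched
structure towards a near-singular point but keeps the deformation
invertible.

## Command line

```
dmorphons phantom scaled-disk -o ph/                 # write a phantom pair
dmorphons register ph/fixed.nii ph/moving.nii \
          -o field.nii --method morphons --accumulation diffeomorphic \
          --log iters.csv
dmorphons jacobian field.nii                         # min/max, inverted voxels
dmorphons evaluate --fixed ph/fixed.nii --moving ph/moving.nii \
          --field field.nii --report report.json
dmorphons bank --ndim 2 --rho 1.5708 --size 9 --dump kernels/
```

Volumes are read and written as NIfTI (`.nii`/`.nii.gz`) or MetaImage
(`.mhd`/`.mha`); displacement fields as multi-component NIfTI with the
vector dimension last, in voxel units.

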