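# Methods

`dmorphons` implements nonparametric deformable image registration in a
single multiscale pipeline whose three per-iteration blocks — update-field
computation Θ, field accumulation Φ, and field regularization Ψ — can be
combined into four methods: conventional and diffeomorphic Demons
(intensity-difference updates) and conventional and diffeomorphic Morphons
(local-phase updates with certainty weighting). This note describes the
model, the numerical choices, and what the phantom studies do and do not
demonstrate.

## Images, fields and warping

Images f (fixed) and m (moving) are scalar functions sampled on a regular
voxel grid; the goal is a displacement field D, in voxel units on the fixed
grid, such that m∘Δ ≈ f with Δ = Id + D. Warping uses linear interpolation;
sample coordinates outside the grid are clamped to the nearest in-grid
point, while image *convolutions* use zero padding — two distinct, fixed
conventions. Physical voxel spacing is carried as metadata and used only
for physical-unit reporting (landmark errors in mm); all field arithmetic
is grid arithmetic. Anisotropic spacing therefore affects reporting only —
a documented limitation.

Two fields combine by compositive accumulation,

    D1 ⊕ D2 = D2 + D1 ⋄ D2,      D1 ⋄ D2 = D1 ∘ Δ2,

whose associated deformation is Δ1∘Δ2. The zero field is neutral and ⊕ is
associative up to interpolation error; on smooth fields with 2-voxel
amplitude and ≳12-voxel correlation length the two association orders agree
to better than 0.05 voxel (they differ by second-order interpolation terms,
so rougher fields associate less tightly).

## Exponential of a velocity field

A deformation is guaranteed invertible when it is the time-1 flow of a
smooth stationary velocity field, exp(D). It is computed by scaling and
squaring: choose the smallest k ≥ 0 with ‖2⁻ᵏD‖∞ < 0.5 voxels (`max_step`,
configurable), take the first-order step Id + 2⁻ᵏD, and self-compose k
times. k = 0 reduces to the first-order approximation. The dominant error
is that of the first-order step, which squaring propagates but does not
shrink; it scales like ‖D‖·‖∇D‖·2⁻ᵏ. For the accuracy study we therefore
use an ensemble where this quantity is small but the displacement is not:
128² fields of amplitude 4 voxels with 40-voxel correlation length, tapered
to zero at the boundary. Against a 4096-step explicit Euler integration of
the flow ODE the sup-norm discrepancy is ≈ 0.03 voxel, and
exp(−D) ⊕ exp(D) has sup-norm ≈ 0.07 voxel. The boundary taper matters:
where flow trajectories leave the grid, the result is determined by the
clamping convention rather than by the field, and neither identity holds.

## Quadrature filters and the phase update

Local phase is probed with loglet quadrature filters defined in the
frequency domain by H_η(ω) = χ₊(ηᵀω)(ηᵀω̂)² R(‖ω‖), with
R(r) = exp(−ln²(r/ρ)/ln 2): a one-octave-half-power log-normal radial
envelope peaking at the center frequency ρ, restricted to the half-space in
direction η. Four directions at kπ/4 cover 2D; in 3D we use the six
non-antipodal vertex directions of a regular icosahedron (normalized cyclic
permutations of (0, ±1, φ)), the standard evenly distributed 6-direction
set. Spatial kernels are synthesized by sampling H on a 64-per-axis (2D) /
32-per-axis (3D) DFT grid, inverse transforming, centering, truncating to
`kernel_size` (default 9) per axis and removing the residual DC of the real
part so constant regions give zero amplitude.

Per filter, the dephasing Δϕ_k = arg(q_f q_w*) between the fixed and the
current warped image estimates ρ η_kᵀd of the residual displacement d, valid
while |ρ η_kᵀ d| < π — the multiscale pyramid keeps per-scale residuals
inside this capture range. The certainty c_k = A_f A_w (product of response
amplitudes, with A_w taken from the warped image, since Θ is a function of
(f, w)) weighs a per-voxel weighted least squares

    d = argmin Σ_k [c_k (ρ η_kᵀ d − Δϕ_k)]²,

solved in closed form via the normal equations; voxels whose normal matrix
is numerically singular (smallest eigenvalue < 1e−9 of the largest, or all
certainties < 1e−12 of the global maximum) get d = 0. The solve is verified
against an exhaustive two-stage grid search of the same energy (coarse 0.1,
fine 0.01 voxel): agreement to grid resolution over 1000 random instances.
Because arg(·) of a positive real multiple vanishes, the update is
invariant to positive intensity rescaling of either image — the property
the contrast experiments probe. No phase unwrapping is attempted.

The Demons comparator uses the classical intensity-difference update
d = (f − w)∇f /(‖∇f‖² + (f − w)²), zero where the denominator vanishes. Its
certainty is identically 1: it runs through the same Φ/Ψ machinery but with
undamped accumulation and uniform-certainty (plain Gaussian)
regularization, matching the published Demons baseline, which has no
certainty concept.

## Accumulation and regularization

Morphons damps each update per voxel by w = c_u/(c_a + c_u) using the
accumulated certainty c_a, which itself accumulates as
(c_a² + c_u²)/(c_a + c_u) — bounded by max(c_a, c_u), so stale certainty
fades. Three accumulation modes are provided:

* additive: D_a + w·D_u (the conventional scheme; inconsistent with
  composition and able to fold),
* compositive: D_a ⊕ (w·D_u),
* diffeomorphic: D_a ⊕ (exp(w·D_u) − Id) — every increment is a flow, so
  the accumulated deformation is a composition of diffeomorphisms.

Regularization is normalized convolution: each field component is smoothed
as ((c_a·s) ∗ g)/(c_a ∗ g) with a Gaussian g of variance σ_Ψ² = 2 voxels
(default; truncated at 4σ, zero-padded so certainty outside the volume is
zero), then the certainty itself is smoothed the same way. This propagates
displacements from high- to low-certainty regions and never increases a
component's sup-norm; where the denominator falls below 1e−12 of its
maximum the output is set to zero.

## The multiscale driver

Coarse-to-fine over scales j = J..0: images are antialias-smoothed
(Gaussian, σ = κʲ/2, edge-replicating so constants are preserved) and
decimated by κʲ (κ = 2). At each scale the loop warp → Θ → Φ → Ψ runs for
at least 10 and at most 20 iterations, stopping early when the relative SSD
change on the current scale's grid drops below 0.01%. Fields (and, for
Morphons, the accumulated certainty, initialized to zero at the coarsest
scale) are transferred to the next finer grid by linear interpolation with
vector magnitudes multiplied by κ. The same filter bank is used at every
scale, which probes a one-octave-higher image band each coarsening. J is
auto-capped so the coarsest grid spans at least two kernel widths per axis.
The driver is deterministic; randomness exists only in phantom generation.

## Phantoms and what the studies show

* **Scaled-disk pair** (128², radius 30, blur σ 2; moving = 0.75 × fixed
  elementwise): identical geometry, different contrast. The Morphons
  update is zero to rounding (≈1e−9 voxel: the dephasing of an exact
  positive multiple is analytically zero; FFT-based convolution leaves
  machine-epsilon residue) and full Morphons registration returns a field
  with mean magnitude ~1e−15 voxel, while Demons builds a >3-voxel rim
  field trying to equalize intensities.

* **Hole-disk pair** (fixed: disk of radius r1+r2 = 40 with a bright
  central hole of radius r2 = 10, intensities annulus ½ / center 1 after
  blurring; moving: disk of radius r1 at the annulus intensity): a
  structure present only in the fixed image. Both accumulations reach the
  same image match, but the central correspondence is ambiguous. This
  experiment uses ρ = π/8 with a 25-voxel kernel: the ambiguity is only
  *perceived* when the filter wavelength (2π/ρ = 16 voxels) is comparable
  to the 20-voxel gap between the hole boundary and its nearest
  phase-matching structure (the moving rim) — at the package's default
  ρ = π/2 every configuration we tried converges to a smooth, everywhere-
  invertible stretch and the contrast between accumulation modes never
  appears. In the long-wavelength regime, additive accumulation folds
  (min Jacobian ≈ −0.16) while diffeomorphic accumulation compresses the
  hole toward a near-singular but invertible point (min Jacobian ≈ +0.06,
  "close to zero" at the center), at identical SSD.

* **Textured pair** (256² band-limited smoothed noise with an embedded
  blob, apodized to a quiet border band the way anatomy fades to air at a
  scan edge): warped by exp(−V) for a smooth random V with ‖V‖∞ = 4 voxels
  and 12-voxel correlation length, so that registering the pair should
  recover exp(V) directly. The moving image is synthesized with cubic
  resampling: the generator emulates a continuous scene and must be more
  accurate than the linear interpolation under test, otherwise the
  measured SSD floor is dominated by the generator's own resampling loss.
  Diffeomorphic Morphons recovers the field with mean endpoint error
  ≈ 0.08 voxel over the full-contrast support and leaves ≈ 2–3% of the
  initial SSD. An optional local intensity rescaling inside the blob
  emulates contrast enhancement.

What passing these studies does *not* show: performance on real CT
(noise, artifacts, sliding motion, cross-resolution acquisition), behavior
under intensity relationships that are not locally multiplicative, or
accuracy for deformations rougher than the filter capture range per scale.
The phantom deformations are exponentials of smooth fields — exactly the
model class the diffeomorphic accumulation assumes.

## Defaults worth knowing

| Parameter | Default | Meaning |
| --- | --- | --- |
| `rho` | π/2 rad/voxel | filter center frequency (per-scale capture range π/ρ voxels) |
| `kernel_size` | 9 | spatial kernel extent per axis |
| `sigma_psi_sq` | 2 voxels² | variance of the regularization Gaussian |
| `subsample` | 2 | pyramid decimation factor κ |
| `min_iters`/`max_iters` | 10 / 20 | per-scale iteration bounds |
| `ssd_rel_tol` | 1e−4 | 0.01% relative-SSD stopping rule |
| `max_step` | 0.5 voxels | scaling rule of the field exponential |

Degenerate inputs: grids under 3 voxels per axis are rejected for
differential metrics; empty masks, non-binary masks, negative certainties,
and mismatched grids raise `ValueError`. Where a damping weight would be
0/0 (no certainty anywhere) the update is ignored.

## Known limitations

Fields compose in voxel units on equal-shape grids; cross-resolution pairs
must be resampled beforehand. The inverse of a field is available only as
exp(−V) when the velocity is known. Boundary behavior is governed by
coordinate clamping; quantities within a kernel width of the volume edge
are less reliable. The additive mode is provided as a comparator and can
produce non-invertible fields by design.
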