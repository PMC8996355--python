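# Methods

## Model

Registration of a moving volume `I_m` to a fixed volume `I_f` is
parameterized by a stationary velocity field (SVF) `v`: the deformation is
the time-1 flow `Φ(v)` of `dD/dt = v(D)`, `D(0) = Id`. The flow is computed
by scaling and squaring: `v` is divided by `2^K` and the resulting small
displacement is self-composed `K` times (`K = 7` by default). Because the
flow of `−v` is the inverse map, forward and inverse deformations come from
the same field, and inverse consistency is a measured property rather than
an extra constraint.

The velocity field is built coarse to fine in `L = 3` increments. Three
convolutional sub-networks take the (moving-or-warped-moving, fixed) pair at
full resolution and regress incremental SVFs on grids at 1/8, 1/4 and 1/2 of
the input resolution; each shares a four-layer stride-2 encoder
(16, 32, 32, 32 filters) and has 1, 2 or 3 stride-2 transposed-convolution
layers (32 filters), a head of 32- and 16-filter convolutions, and a
3-channel output convolution. Kernels are 3×3×3 throughout; activations are
LeakyReLU with slope 0.2 except on the output. The output convolutions are
zero-initialized so the untrained model is exactly the identity transform.
No skip connections are used: the sub-networks are encoder–decoder chains.

Increments accumulate as `ṽ_1 = v_1`, `ṽ_l = upsample(ṽ_{l−1}) + v_l`.
Vectors are stored in full-resolution voxel units at every level, so the
accumulation is plain addition; when a field is integrated or applied on a
coarser grid its values are divided by the grid scale. For level `l > 1` the
moving image is first warped (at full resolution) by the integrated
`Φ(ṽ_{l−1})`, so each sub-network sees only residual misalignment. The final
displacements integrate `±ṽ_L` upsampled to the full grid and then pass
through an in-graph Gaussian smoothing layer (σ = 1.732 voxels, 3³ kernel,
renormalized after truncation, replicate borders). Smoothing is part of the
trained computation graph, not a post-process.

## Objective

Each level contributes a bidirectional similarity term and a regularizer:

    Σ_l  −NCC(I_f^l, I_m^l ∘ Φ(ṽ_l)) − NCC(I_m^l, I_f^l ∘ Φ(−ṽ_l)) + λ TV(v_l)

plus, by default, the same bidirectional similarity at full resolution using
the smoothed final fields. Image pyramids are built by recursive 3×3×3
average pooling with stride 2 (replicate padding, exact halving).

*NCC.* The default similarity is local windowed zero-normalized
cross-correlation with 9³ windows, computed from window sums via separable
box filters; `ε = 1e-5` is added to the variance product before the square
root, which is negligible for textured windows and guards flat ones. A
`"global"` Pearson mode is available. Window statistics as sums (not means)
matter: with means, the ε guard dominates realistic local variances and the
similarity loses nearly all sensitivity to alignment.

*TV.* The regularizer is the mean over voxels and vector components of the
L1 norm of forward differences, summed over the three axes, with the
differences divided by the grid step in full-resolution voxel units. Two
normalization choices deserve note. First, dividing differences by the grid
step makes the penalty a consistent estimate of |∇v| at every level, so one
λ applies across resolutions. Second, averaging over components (not only
voxels) calibrates the λ axis so that λ = 0.35 is the operating point where
Dice is maximal subject to zero folding on the package's benchmarks — the
same selection rule used to pick that value in the first place; with a
sum-over-components convention the equivalent knee sits near λ ≈ 0.1 and the
published weight would over-regularize.

## Training and instance optimization

Training draws uniformly from the n² ordered pairs of a volume set
(self-pairs included), normalizes intensities to [0, 1] per volume,
symmetrically zero-pads to the next multiple of 16, and takes one Adam step
(β = 0.9/0.999, ε = 1e-8) per pair with batch size 1. The full-scale profile
uses learning rate 1e-4 and 150 000 iterations. The **desk profile**
(`TrainConfig.desk()`) targets 32–64³ inputs and hundreds of iterations;
its learning rate is 3e-3, chosen so that instance optimization converges
within that budget (with zero-initialized output layers, early updates act
almost solely on the output convolutions, and at 1e-4 the velocity scale
reachable in a few hundred steps is far below a voxel). All randomness flows
through explicit seeds; on a single CPU thread runs are bitwise
reproducible.

Instance optimization (`register_pair(..., "instance")`) fits fresh network
parameters to a single pair with the same objective — conventional iterative
registration with a network-parameterized transform. Feedforward mode reuses
trained weights with no optimization.

## Synthetic study conditions

The generator emulates skull-stripped, affinely aligned T1 volumes with
phantoms of nested ellipsoidal shells (random per-seed axes, orientation and
center for inter-subject variability), piecewise-constant tissue intensities
modulated by a smooth multiplicative texture (amplitude 0.3, correlation
length 2 voxels — standing in for the tissue texture and intensity
inhomogeneity that give local NCC its signal away from boundaries), light
Gaussian blur (σ = 1) and additive noise (SD 0.02). Ground-truth warps are
Gaussian-smoothed white-noise SVFs rescaled to a prescribed peak magnitude,
with the magnitude distribution compressed toward the peak (exponent 0.5) so
the deformation is substantial across the volume, and re-drawn until the
integrated warp has a strictly positive Jacobian everywhere.

Two standard conditions are used by the tests and the acceptance script:

* **recovery benchmark** — 48³, five shells, warp amplitude 4 voxels,
  smoothness 4 voxels: initial mean label Dice ≈ 0.70; instance
  optimization (300 iterations, λ = 0.35) recovers ≈ 0.87 in both
  directions with zero folding voxels inside the phantom;
* **small benchmark** — 32³, four shells, amplitude 3, smoothness 3.5: used
  for the λ trade-off (0.1 vs 1.0, three seeds — TV of the accumulated
  velocity decreases with λ, folding does not increase) and the
  smoothing-layer ablation (with-vs-without smoothing at λ = 0.35, three
  seeds — folding never decreases when smoothing is removed), at 120
  iterations per run.

What the phantoms do **not** model: MR acquisition physics, bias fields
with realistic spatial structure, fine cortical geometry, topological
differences between subjects, or pathology. Passing these benchmarks shows
the machinery — integration, multi-resolution estimation, bidirectional
training, smoothing and evaluation — behaves as designed at desk scale; it
does not certify registration accuracy on clinical data, which depends on
population-scale training at full resolution.

## Numerical choices and degenerate inputs

* Interpolation is trilinear with clamp-to-border sampling everywhere
  (images and fields); label maps use nearest neighbor. Clamping avoids
  injecting background zeros into NCC statistics; it also zeroes position
  gradients at the border.
* Field upsampling maps grid corners to grid corners, so nodes of an
  axis-aligned refinement reproduce source values exactly; vector values
  are never rescaled by the resolution change.
* The Jacobian determinant uses central differences in the interior and
  one-sided differences on faces, applied to the full map `x + u(x)`; the
  folding count reports voxels with determinant ≤ 0 inside a mask
  (default: the nonzero support of the fixed image, a faithful brain-region
  proxy for skull-stripped inputs).
* The 3³ kernel truncates the σ = 1.732 Gaussian heavily; the kernel is
  renormalized per axis to sum to 1, so constant fields are preserved.
* Scaling-and-squaring error: against 1024-step Euler integration of the
  same flow, seven steps agree to < 0.05 voxels (max, interior) for smooth
  fields with |v| ≤ 2 voxels on 24³ grids; boundary voxels are excluded
  because clamped sampling distorts the flow there by construction.
* Constant-intensity volumes normalize to zero and correlate to 0 under the
  ε guard rather than raising; empty masks and mismatched grids raise
  `ValueError`.
* Integration with `steps < 1`, even smoothing kernels, level counts other
  than 1–3 and shrinking "upsample" requests are rejected.

## Known limitations

* Deformation composition assumes a single common grid in voxel units;
  there is no physical-space (mm) composition across differently oriented
  grids (fields can be exported in mm).
* Velocity fields are stationary; time-varying parameterizations are out of
  scope.
* The similarity is mono-modal (NCC); no mutual information.
* The autodiff core materializes the full graph per iteration; memory is
  ample at desk scale but full-resolution (176×192×176) training, while
  functional, is far slower than a GPU implementation of the same model.
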