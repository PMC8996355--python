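# mdreg — multi-resolution diffeomorphic image registration

`mdreg` registers pairs of 3-D volumes (NIfTI) with a self-supervised,
multi-resolution convolutional model parameterized by **stationary velocity
fields** (SVFs). It is aimed at deformable registration of skull-stripped,
affinely aligned brain MR volumes — and at anyone who needs dense, invertible
deformations with an explicit handle on foldings.

## The model

Deformable registration seeks a deformation `D` maximizing image similarity
under a smoothness penalty:

    min_D  −S(I_f, I_m ∘ D) + λ R(D)

`mdreg` represents `D = Φ(v)` as the time-1 flow of a stationary velocity
field, integrated by **scaling and squaring** (7 time steps), which makes the
deformation (near-)diffeomorphic and gives the inverse for free as `Φ(−v)`.
The velocity field is estimated **coarse to fine**: three convolutional
sub-networks predict incremental SVFs `v_1, v_2, v_3` at 1/8, 1/4 and 1/2 of
the image resolution, accumulated as `ṽ_l = Σ_{i≤l} v_i`. Training is
self-supervised with deep supervision at every level and in both directions:

    min_{v_l} Σ_l [ −NCC(I_f^l, I_m^l ∘ Φ(ṽ_l))
                    −NCC(I_m^l, I_f^l ∘ Φ(−ṽ_l)) + λ TV(v_l) ]

where the image pyramids come from 3×3×3 average pooling, NCC is local
windowed normalized cross-correlation (9³ windows by default), and TV is the
L1 norm of the velocity gradients. A Gaussian **smoothing layer**
(σ = 1.732 voxels, 3³ kernel) is part of the model at the finest resolution,
pushing the learned deformations toward fold-free (Jacobian determinant > 0
everywhere). The default trade-off weight is λ = 0.35.

The whole chain — sub-networks, integration, warping, smoothing, losses — is
differentiated end to end by a compact reverse-mode autodiff core for dense
3-D arrays (`mdreg.autodiff`), with the trilinear gather/scatter kernels JIT
compiled via numba.

Two ways to register:

* **feedforward** — train once on a population (`mdreg train`, n² ordered
  pairs, Adam, batch 1), then register new pairs in a single forward pass;
* **instance optimization** — fit fresh network parameters to one pair only
  (`mdreg register --instance`), i.e. conventional iterative registration
  with a network-parameterized transform.

## Worked example

Generate a synthetic pair (a 48³ five-shell phantom deformed by a known
fold-free warp with 4-voxel peak displacement), register it by instance
optimization, and evaluate the propagated labels:

```python
from mdreg.synthetic import recovery_benchmark_pair
from mdreg.training import TrainConfig, register_pair
from mdreg.evaluation import brain_mask, dice_scores, evaluate_direction

fixed, moving, labels_f, labels_m, gt_svf = recovery_benchmark_pair(seed=7)
print("initial dice:", dice_scores(labels_m, labels_f)[1])

cfg = TrainConfig.desk(iterations=300, lam=0.35, seed=7)
result = register_pair(fixed, moving, "instance", cfg)

fwd = evaluate_direction(result, labels_f, labels_m, "forward",
                         mask=brain_mask(fixed))
inv = evaluate_direction(result, labels_f, labels_m, "inverse",
                         mask=brain_mask(moving))
print("forward dice:", fwd.mean_dice, "foldings:", fwd.folding_count)
print("inverse dice:", inv.mean_dice)
```

Output (about five minutes on one CPU core):

```
initial dice: 0.7022
forward dice: 0.874  foldings: 0
inverse dice: 0.874
```

The warp degrades the label overlap from 1.0 to 0.70; registration recovers
mean Dice 0.87 in both deformation directions with **zero** voxels of
non-positive Jacobian determinant inside the phantom — the invertibility the
SVF parameterization plus smoothing layer is designed to deliver.

The same workflow from the shell:

```bash
mdreg synth --shape 48 --amplitude 4 --seed 7 --out fixture/
mdreg register --fixed fixture/fixed.nii.gz --moving fixture/moving.nii.gz \
               --instance --iters 300 --seed 7 --out result/
mdreg evaluate --result result/ --labels-fixed fixture/labels_fixed.nii.gz \
               --labels-moving fixture/labels_moving.nii.gz --direction both
```

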