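# proreg — progressive self-calibrating deformable 3D registration

`proreg` registers pairs of pre-affined 3D grayscale volumes (e.g. brain
images) by estimating a dense displacement-vector field (DVF) with an
unsupervised, shared-weight convolutional network applied *progressively*.
It is aimed at the residual **large non-linear deformations** that survive
global affine pre-alignment, which one-shot registration networks handle
poorly because the smoothness penalty caps how far any single predicted
field can move a structure.

## The method

Let `M` and `F` be the moving and fixed volumes. A UNet `G` with one
shared parameter set is applied for `n` passes. Pass `k` predicts a
residual field from the *previous pass's warped output*:

    u_k = G(warped_{k-1}, F),        warped_0 = M

so the network learns to correct its own remaining error
("self-calibration"). Instead of warping the warped image again — which
blurs structure boundaries a little more at every interpolation (the
*information loss* of conventional cascades) — the per-pass fields are
folded algebraically into one total field with the aggregation rule

    u_total(x) = u_next(x) + u_prev(x + u_next(x))

(because `(M∘φ_prev)∘φ_next = M∘φ_total` with `φ(x) = x + u(x)`), and the
*primary* moving image is interpolated **exactly once** per output.

Training minimizes, per pass,

    Loss = −LNCC(warp(M, u_total), F) + λ · ‖∇u_n‖² ,

a local normalized cross-correlation similarity plus a diffusion
(smoothness) penalty on the newest per-pass field only. A two-scale
coarse-to-fine cascade first registers 2×-downsampled volumes, then
upsamples the coarse flow (doubling both the grid and the displacement
values) to initialize the full-resolution chain. The pass counts
`n_train` and `n_test` are independent hyperparameters; at full scale the
grid-searched optima are 5/3 (low scale) and 9/2 (original scale).

Everything runs on the CPU: the network, its reverse-mode gradients, and
the Adam training loop are implemented directly over numpy
(`proreg._autodiff`), with convolutions lowered to BLAS matrix products.

## Worked example

No data downloads are needed — the package generates labeled brain-like
phantoms with smooth random ground-truth deformations:

```bash
proreg generate --out pair --shape 32,32,32 --preset large --seed 0
```

writes `fixed.nii.gz`, `moving.nii.gz`, label maps, and the ground-truth
flow `u_gt.nii.gz`. The `large` preset calibrates the deformation
amplitude so the smallest labeled structure starts below the Dice 0.6
"large deformation" threshold. Train the two-scale cascade and register:

```python
import dataclasses, numpy as np, proreg as pr
from proreg.progressive import TrainConfig, IterationSchedule
from proreg.losses import LossWeights

pspec = pr.PhantomSpec(shape=(32, 32, 32), seed=0)
dspec = pr.calibrate_severity(pspec, (0.0, 0.5), which="smallest", seed=100, n_fields=4)
pairs = [pr.make_pair(dataclasses.replace(pspec, seed=i),
                      dataclasses.replace(dspec, seed=200 + i)) for i in range(8)]
test = [pr.make_pair(dataclasses.replace(pspec, seed=50 + i),
                     dataclasses.replace(dspec, seed=300 + i)) for i in range(4)]

cfg = dict(learning_rate=1e-3, weights=LossWeights(1.0, lncc_window=5))
low, orig, *_ = pr.train_hierarchical(
    pairs,
    TrainConfig(steps=150, schedule=IterationSchedule(3, 3), **cfg),
    TrainConfig(steps=150, schedule=IterationSchedule(3, 2), **cfg))

for p in test:
    res = pr.hierarchical_infer(p.moving, p.fixed, low, orig,
                                IterationSchedule(3, 3), IterationSchedule(3, 2))
    warped_labels = pr.warp_labels(p.moving_labels, res.total_flow)
    print(round(pr.dice_report(p.moving_labels, p.fixed_labels).mean, 3),
          round(pr.dice_report(warped_labels, p.fixed_labels).mean, 3),
          res.interp_count)
```

On this fixture the run prints (about 4 minutes on one CPU core):

```
0.579 0.749 1
0.565 0.753 1
0.672 0.749 1
0.62 0.728 1
```

per held-out pair: mean Dice over the four labeled structures before
registration, after registration, and the number of interpolations that
produced the output — always 1, the method's defining property. Mean Dice
rises from 0.61 to 0.74 on these large-deformation phantoms.

The `register`, `evaluate`, `compose`, and `gridsearch` subcommands expose
the same operations on NIfTI files; flows are stored as 4D NIfTI with a
trailing dimension of 3 (displacements along the array axes D, H, W, in
voxel units — the header `descrip` field records the convention).

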