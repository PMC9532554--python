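# Methods

## Problem setting and model

`proreg` performs unsupervised deformable image registration (DIR) of
pre-affined 3D volumes. The transformation model is a dense
displacement-vector field (DVF) `u` on the voxel grid; the deformation is
`φ(x) = x + u(x)` and warping is *backward*: `warped(x) = M(φ(x))`,
sampled trilinearly. The deformation field is never stored separately —
`φ` is always formed on demand from `u`.

A single UNet `G` with one shared parameter set predicts a residual DVF
from a (moving, fixed) pair. Registration is progressive: pass `k`
predicts `u_k = G(warped_{k-1}, F)` where `warped_{k-1}` is the previous
pass's output, so the network repeatedly corrects its own residual error
(self-calibration). The per-pass fields are combined by the aggregation
rule

    compose_pair(u_prev, u_next)(x) = u_next(x) + u_prev(x + u_next(x)),

the exact identity satisfied by sequentially applied backward warps of
continuous fields. A chain of `n` fields folds left into one total field
with `n − 1` pairwise aggregations, and the *primary* moving image is
interpolated once with the total field. A conventional cascade
(`cascade_infer`) that re-warps the warped image each pass is kept for
comparison: it applies `n` interpolations and measurably blurs structure
boundaries, which is the information-loss effect the aggregation avoids.

The two-scale mode downsamples both volumes ×2 (average pooling), runs
the progressive chain with a low-scale network, upsamples its total flow
(trilinear, cell-aligned) and multiplies the displacement values by 2 to
convert them to fine-grid voxel units, then uses that field to initialize
the full-resolution chain. The upsampled flow is *aggregated into* the
full-resolution total (not merely used to pre-warp), which preserves the
single-interpolation property end-to-end.

## Objective

Per pass `n` the training loss is

    Loss = −LNCC(warp(M, u_total), F) + λ · L_smooth(u_n)

* **LNCC** — local normalized cross-correlation over cubic windows
  centered at every voxel and truncated at the volume borders; signed
  (not squared), with a variance guard ε = 1e−5 added under the square
  root of the denominator. It is bounded in [−1, 1] and invariant to
  positive affine intensity maps. Both inputs are conditioned to [0, 1]
  by a constant min–max map before the window statistics are formed —
  analytically a no-op (NCC is affine-invariant) but numerically
  essential for 8-bit-range intensities, where the windowed variance
  cancellation otherwise loses all significant digits in float32. Window
  sums are accumulated via float64 prefix sums for the same reason.
* **L_smooth** — squared forward differences of the DVF over all voxels,
  components and axes, **normalized by the number of difference terms**
  (mean form) so λ is comparable across resolutions; λ defaults to 1.0
  at the desk scale. The penalty acts on the newest per-pass field
  `u_n` only, never on the aggregate: the aggregate legitimately grows
  large over passes, and penalizing it would re-impose exactly the cap
  on total displacement that progressive registration exists to remove.

## Training procedure

Default update granularity is **one Adam update per pass**: the previous
warped image and the running aggregate enter the graph as constants, only
the newest field carries gradients, and the update fires as soon as the
pass's objective is evaluated. A `per_sweep` mode (sum gradients over all
passes, one update) is available via `TrainConfig.update`. Batch size 1.

Two-scale training is sequential: phase 1 trains the low-scale network on
downsampled pairs; phase 2 freezes it and trains the full-resolution
network, each step initialized by the frozen low-scale output exactly as
at inference. `n_train` and `n_test` are independent; `grid_search`
trains one model per `n_train` and evaluates each at every `n_test`,
returning the mean-Dice matrix and its argmax. Because pass `k` trains on
the warped output of pass `k − 1`, each added training pass implicitly
enlarges the training distribution — the sweep therefore doubles as the
dynamic-augmentation experiment; no explicit augmentation operator
exists.

### Scales and defaults

| parameter | desk scale (tests, acceptance script) | full scale |
|---|---|---|
| volume shape | 32³ (low scale 16³) | 192×160×192 |
| LNCC window | 5 | 9 |
| learning rate | 1e−3 | 1e−4 |
| steps per scale | 150 | 30 000 |
| n_train/n_test | 3/3 low, 3/2 original | 5/3 low, 9/2 original |
| λ | 1.0 | tuned per dataset |

Desk-scale problem sizes were chosen so a full two-scale training runs in
a few minutes on one CPU core while still showing a clear registration
effect (held-out mean Dice rises by ~0.1 over the affine-only baseline on
the large-deformation fixture). The full-scale values remain reachable
through the same configuration objects. The desk learning rate is higher
because the run is two orders of magnitude shorter; with 1e−4 and 150
steps the network barely leaves its initialization.

## Network

Encoder: one 4×4×4 stride-2 convolution per stage (default 4 stages,
widths 16-32-32-32). Decoder: per stage, nearest ×2 upsampling,
concatenation with the matching encoder feature (the 2-channel input pair
itself at full resolution), then 3×3×3 stride-1 convolutions; the last
two stages apply two such convolutions (widths 32-32-32-16-16). All
convolutions are followed by LeakyReLU (slope 0.2) except the final
3×3×3 flow head, whose weights are initialized with std 1e−5 so the
untrained network starts at (essentially) the identity transform — this
keeps the first progressive passes from amplifying noise. Network inputs
are min–max rescaled to [0, 1] per volume. Channel widths and stage count
are configurable; the defaults are the smallest configuration that
trains reliably on 32³ fixtures.

The network, its gradients, and Adam are implemented over numpy in
`proreg._autodiff`, a compact reverse-mode engine covering exactly the
operator set this model needs (shift-and-matmul 3D convolution, nearest
upsampling, concatenation, box-window sums, forward differences, and
trilinear resampling at flow-displaced coordinates with analytic
coordinate gradients). Every operator is validated against central finite
differences in the test suite. This keeps the package CPU-only and
dependency-light.

## Numerical and geometric conventions

* 0-based voxel coordinates, voxel centers at integers, displacements in
  voxel units; these make the ×2 rescaling of upsampled flows
  self-consistent.
* Out-of-bounds samples clamp to the boundary (clamp-to-edge) for both
  intensities and flows; the flow gradient is zero where a coordinate
  clamps. Zero padding would inject spurious zero displacements into
  composed flows near borders.
* Label maps warp by nearest-neighbor lookup with the `floor(c + 0.5)`
  tie rule (exact half-voxel displacements round up).
* Downsampling is 2×2×2 average pooling (exact for constants,
  antialiasing). Flow upsampling uses the cell-aligned mapping
  `x_low = x_fine/2 − 0.25`, consistent with the pooling grid.
* Composition resamples the previous aggregate with the same trilinear
  sampler and clamp policy as image warping. The composed lattice field
  is interpolated, so compose-then-warp and warp-twice differ by a term
  that is second order in field curvature; composition tests therefore
  use gentle fixtures (peak displacement ≲ extent/8, Gaussian smoothness
  σ ≥ 2) and exclude a 2-voxel border margin. No diffeomorphism or
  inverse-consistency constraint is enforced — composed fields may fold;
  only the smoothness penalty discourages it, as during training.
* Dice of two empty masks is defined as 1; the report mean is unweighted
  across labels.
* Edge sharpness is the mean forward-difference gradient magnitude over a
  caller-supplied band of boundary-adjacent voxels; it operationalizes
  "boundary blurring" so the single-warp vs. cascade comparison is a
  number rather than a visual impression.

## Synthetic data

`make_phantom` builds one bright outer ellipsoid ("brain") containing
`n` non-overlapping ellipsoidal structures with distinct labels and mean
intensities, Gaussian-smoothed; one structure is deliberately small
(radius ≈ 2 voxels) to mimic the size spread of real anatomy and give
severity calibration a sensitive target. `random_smooth_flow` is
Gaussian-smoothed white noise rescaled so its peak displacement norm
equals the requested amplitude. `make_pair` forms `moving =
warp(fixed, u_gt)` — the simplest forward model whose recovery is
measurable by Dice and LNCC without inverting a field. Generation is a
pure function of the spec seeds (layout rejection-sampling retries are
deterministically reseeded), so fixtures are byte-reproducible and no
data files ship with the package.

Severity is expressed in overlap, not voxels: initial Dice below 0.6 for
the smallest structure is the conventional threshold for a "large"
deformation (0.8 for large structures). `calibrate_severity` bisects the
amplitude until a chosen structure's initial Dice lands in a requested
band, optionally averaging over several seeded fields (`n_fields`) since
a single field's peak location makes one-field calibration noisy. The
`large` preset targets Dice ≈ 0.5 — the interior of the regime — so pairs
sampled with fresh field seeds still average below the 0.6 threshold.

What the phantoms do **not** emulate: imaging texture and noise,
intensity non-uniformity, multi-modal contrast, anatomically realistic
shapes, or folding/topology-breaking deformations. Passing tests
demonstrate that the machinery (aggregation, self-calibrating training,
two-scale transfer, evaluation) works and that the method's comparative
claims hold on controlled geometry; they do not certify accuracy on real
brain data.

## Known limitations

* CPU-only and desk-scale by default; full-scale runs are configured but
  slow without hardware acceleration.
* Mono-modal similarity only (LNCC); multi-modal registration is out of
  scope.
* No affine pre-alignment: inputs are assumed globally registered
  upstream.
* Composed flows are not guaranteed invertible; no folding diagnostics
  are computed.
* Boundary behavior under clamping is implementation-defined within a
  2-voxel margin.
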