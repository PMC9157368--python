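# Methods

This package reimplements a dual-task deep segmentation pipeline for 3D plant
point clouds: per-point *organ semantics* (stem vs. leaf, per species) and
per-leaf *instances*, trained jointly and extracted with mean-shift
clustering.  Because no public accession of the original laser-scanned crop
dataset exists, the package ships a synthetic-plant generator so that every
stage — sampling, network, losses, inference, metrics — is exercised end to
end on data with the same statistical structure.

## Sampling: FPS, VBS, VFPS

Farthest-point sampling (FPS) greedily adds the point with the largest
minimum distance to the selected set (ties to the lowest index, so results
are reproducible).  Voxel-based sampling (VBS) replaces each occupied voxel
with the centroid of its members; labels transfer by per-voxel majority vote
(ties to the lowest id), with the centroid's semantic class derived from its
voted instance so that an instance never straddles organ classes.

VFPS chains the two: voxelize to *slightly more* centroids than the target
N, then FPS down to exactly N from a seed-chosen start centroid.  The voxel
edge is auto-tuned by bisection on a single isotropic edge length over
`[bbox_diag/1000, bbox_diag]`, accepting the first grid whose occupied-voxel
count lands in `[N, 1.3 N]` (otherwise the smallest count ≥ N encountered).
The grid origin is the bounding-box minimum corner, making the construction
translation-invariant.  Repeated draws with consecutive seeds give the
augmentation used for training (the only randomness is the FPS start).

## Synthetic plants

Three morphologies in millimeter units, chosen to mirror how real crops
differ:

* **broadleaf** (tobacco-like): 4–7 large elliptical blades (~0.8 × leaf
  size, quadratic cupping) on a short stem (~240 mm);
* **compoundleaf** (tomato-like): 5–9 pinnate leaves, each one terminal plus
  two lateral leaflets sharing one instance id, on a taller stem (~320 mm);
* **slenderleaf** (sorghum-like): 5–9 long twisted straps (2–3 × leaf size
  long, ~30% as wide) on a tall stem (~420 mm).

Stems are thin tubes along a smoothly bowed vertical curve; leaves attach at
distinct stem nodes with golden-angle azimuths.  A height-proportional
thinning factor (`density_gradient`) reproduces the dense-bottom/sparse-top
imbalance of real scans, and isotropic Gaussian noise (default 0.05 mm)
models scanner error.  Semantic ids are fixed at C = 6 (stem/leaf × 3
species); all stem points share one reserved instance id that leaf-instance
evaluation ignores.  Stems are a minority of points (< 30%), as in real
data.  What the generator does **not** model: self-occlusion, scanner
viewpoint effects, petiole/rachis geometry, leaf venation, and seedling-scale
degenerate plants — so passing tests demonstrate pipeline correctness and
desk-scale learnability, not field performance.

## Network

A four-level encoder; before each block the point set is farthest-point
subsampled (4096 → 1024 → 512 → 256 → 128 at full scale).  The FPS start
point is the extreme point along a seeded random direction — seeded *and*
permutation-equivariant, unlike a random index.  Each block runs three
stages combining two neighborhoods:

* *position encoding* of the XYZ k-NN of each point (10-d:
  `p ∪ p_k ∪ (p − p_k) ∪ ‖p − p_k‖`), computed once per block;
* *EdgeConv* over the k-NN of the current feature space
  (`MLP(f ∪ (f − f_k))`), recomputed each stage;
* *attentive pooling*: softmax-scored weighted sum of the concatenated
  features, then a pointwise MLP.  The scoring map carries no bias (softmax
  is shift-invariant, a bias would be a dead parameter).

Stage skips: stage-1 output is concatenated onto stage-2's to feed stage 3;
stage-2's output is added residually to stage-3's; stage 1 has no skip.
K = 16 for the first two blocks, 8 for the last two.

Two parallel decoders interpolate back to full resolution with
inverse-distance-weighted 3-NN interpolation and per-level skip
concatenation: a *fine* decoder visiting every level (4 hops) and a *coarse*
one visiting every other level (2 hops).  Their outputs are fused
(concatenation of both maps and their average, pointwise convolution, ReLU)
into the fused feature map (N × 128 at full scale), which also receives the pairwise hinge
supervision below.  Each task branch applies spatial attention (sigmoid of
the per-point channel mean, parameter-free) then channel attention (mean-
and max-pooled 1 × D summaries through two pointwise convolutions, summed,
sigmoid), with branch-specific parameters, and ends in a pointwise head:
N × 5 instance embedding and N × C semantic logits.

Inputs are centered per cloud and scaled to the unit sphere (a fixed
millimeter divisor is available via ``coord_scale`` but measured worse for
held-out species recognition at desk scale).  The layer stack is plain
linear + ReLU: batch-normalization variants were evaluated and removed —
per-cloud feature standardization makes every point's features depend on the
cloud's organ composition, and running-statistics batch norm oscillates when
each forward pass is a single cloud; both degraded held-out accuracy.

Channel widths ([64, 128, 256, 512] full scale; fused 128) follow standard
doubling practice; they and the level sizes are configuration, not claims.

### Autodiff

No deep-learning framework is part of the dependency set; the network runs
on a small in-package reverse-mode autodiff core (`plantseg3d.autodiff`) over
float64 numpy — ~15 primitives with broadcasting-aware gradients.  Discrete
structure (k-NN graphs, FPS picks, interpolation neighbors, argmax) is
constant with respect to differentiation, the usual convention for
point-cloud networks.  Finite-difference agreement of the full pipeline
gradient is part of the test suite.

## Losses

* Semantic: cross-entropy on softmax probabilities, log clamped at 1e-12.
  The printed form is a plain sum over points; training uses the mean
  (batch-size-independent learning rates), and the sum is available via
  `reduction="sum"`.
* Instance: discriminative embedding loss with pull margin δ_s = 0.5, push
  margin δ_d = 1.5 (centers repelled to 2δ_d), and a mean-center-norm
  regularizer; weights α = β = 1, γ = 0.001.  Instances with a single point
  contribute zero pull.  Pull and push are invariant to a common embedding
  translation; the regularizer deliberately is not.
* Pairwise double hinge on the fused feature map: same-instance pairs contribute their
  feature distance, same-class/different-instance pairs a hinge at margin
  1.0, different-class pairs a hinge at margin 2.0; mean over all unordered
  pairs of at most 64 sampled points per cloud per step.  The margins and
  the sampling cap are configuration: the cited formulation leaves them
  open, so they must not be read as reference values.

Total: `L = L_sem + L_ins + L_DHL`.

## Training

Adam (β₁ = 0.9 — the recipe's "momentum" — β₂ = 0.999), batch size 8,
initial learning rate 0.002 multiplied by 0.7 every 10 epochs.  Optional
global gradient-norm clipping exists but is off by default: early push-loss
gradients legitimately exceed small thresholds, and throttling them wastes a
short schedule.  Model selection keeps the parameters with the lowest
*total* test-split loss.  All randomness (batch order, pair sampling,
augmentation) is derived from the master seed and the step index, so a run
resumes from a checkpoint bit for bit.  An optional seeded rigid
augmentation (z-rotation ± mirror) exists but is off by default: rigid maps
preserve every cached neighborhood structure, yet short schedules converge
further without it.

## Inference

Semantics: row-wise argmax (ties to the lowest class).  Instances: flat-
kernel mean-shift in the 5-d embedding, seeds = all points, convergence
tolerance 1e-4, ≤ 300 iterations; modes merged below bandwidth/2 (visited by
decreasing support for determinism); clusters under `max(10, N/500)` points
reassigned to the nearest surviving mode; ids relabeled by decreasing size.
Default bandwidth 0.6 in embedding units, consistent with the δ_s = 0.5 pull
radius.  Each instance receives the majority semantic class of its points
(ties to the lowest id).

## Metrics

Semantic per class: Prec, Rec, F1 (harmonic mean), IoU, in percent.
Instance per leaf class: mCov (mean best-IoU coverage of GT instances),
mWCov (weighted by each GT instance's point share within its class), and
mPrec/mRec counting a prediction as a true positive when its IoU with a
distinct GT instance of the same class strictly exceeds 0.5 (greedy
one-to-one matching by descending IoU; above 0.5 the match graph is
automatically one-to-one, so greedy equals optimal).  Classes absent from
both sides are excluded from means; empty-denominator ratios are undefined
and excluded rather than scored zero.  Test-set reports sum semantic counts
over clouds before taking ratios and weight instance measures by each
cloud's GT instance count, so duplicating a cloud changes nothing.

## Desk-scale profile and problem sizes

The full-scale recipe (4096-point clouds, 190 epochs) needs
accelerator-class compute, so the bundled `toy` profile scales the study
down while keeping its structure: 512-point clouds, encoder levels
[128, 64, 32, 16], widths [16, 32, 64, 128], fused width 32, 3 plants per
species with a 2:1 plant-level split and 4 VFPS draws each, 300 optimizer
steps.  Two schedule quantities are deliberately measured in optimizer steps
rather than toy "epochs" (a 3-step epoch is a scale artifact): the
learning-rate decay interval (no decay falls inside 300 steps, matching the
full-scale recipe's step count) — and nothing else.  The end-to-end checks
assert held-out semantic accuracy and leaf coverage on this profile across
three master seeds.

## Known limitations

* Desk-scale training on 6 source plants generalizes to *one* held-out
  plant per species; per-seed variability is therefore substantial, which is
  why end-to-end checks are posed over multiple seeds.  At this budget the
  semantic task is usually recovered (held-out point accuracy ≈ 0.94–0.95 in
  typical passing seeds), while the 5-d instance embedding remains partially
  fragmented on unseen plants: its within-instance spread has not yet
  contracted below the pull margin after 300 steps, so mean-shift splits
  some leaves and held-out leaf coverage plateaus around the low 60s
  (percent).  Training longer does not close this gap — it overfits the
  embedding to the training plants — so it is a data/budget limit of the
  desk-scale study, not a property of the method at full scale.
* The mean-shift bandwidth is a fixed default, not estimated from data.
* The DHL margins are configuration (see above).
* The generator's species are caricatures: conclusions about real scans
  require real scans.
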