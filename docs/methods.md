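# Methods

This note documents the models and procedures implemented in `spikeseg`,
the numerical choices behind them, what the synthetic phantoms do and do
not emulate, and the known limitations.

## Problem setting

Whole-brain segmentation assigns every voxel of a T1-weighted structural
MRI volume one of C anatomical class labels (class 0 is
background/"unknown").  `spikeseg` implements a Bayesian convolutional
approach to this problem with three goals: fast segmentation, a per-voxel
measure of predictive uncertainty that flags likely errors, and a
volume-level uncertainty summary that predicts manual quality-control (QC)
ratings of the scan.

## Preprocessing pipeline

Every volume is *conformed* — resampled to a 1 mm isotropic cube of 256
voxels per edge (trilinear for intensities, nearest-neighbour for label
volumes) with intensities min-max rescaled to [0, 255] — then individually
z-scored across all voxels (population SD, no masking), and finally split
into 512 non-overlapping 32^3 sub-volumes that the network consumes
independently.  `stitch` is the exact inverse of `tile`: placement is
governed by tile offsets (half-open intervals `[o, o+32)`, lexicographic
order), so tiling followed by stitching is the identity voxel-for-voxel.

Raw label volumes with FreeSurfer-style ids are collapsed to a compact
class set through a two-column lookup table; ids absent from the table map
to background.  The shipped default is a FreeSurfer-aseg-derived 50-class
table; it is a pragmatic stand-in (the canonical 50-class membership is
not fixed by any single source) and fully user-overridable.

## Architecture

The segmentation network is an 8-layer dilated-convolution network
("MeshNet"-style).  All hidden layers use 3^3 kernels with ReLU; the
dilation schedule is (1, 1, 1, 2, 4, 8, 1) and padding equals dilation, so
spatial shape is preserved everywhere.  The read-out layer is a 1^3
convolution onto C classes followed by a per-voxel softmax.  The composed
receptive field is `1 + 2*(1+1+1+2+4+8+1) = 37` voxels per axis — larger
than a 32^3 tile, so voxels near tile borders see zero padding rather than
neighbouring anatomy.  This border property is inherent to the
non-overlapping tiling design and is reproduced, not corrected.

Training consumes pre-softmax scores through a log-sum-exp-stable
cross-entropy; softmax is applied only at prediction time.

## Weight models

Three variants share the one architecture and differ only in how layer
weights are modelled:

**MAP.**  Point weights under a standard-normal prior; training minimizes
cross-entropy plus the L2 penalty `0.5 * sum(w^2)` (biases are
unpenalized).  Prediction is deterministic.

**MC Bernoulli dropout (BD).**  Point weights; a 0/1 mask with keep
probability p (default 0.9, the value selected by validation search over
{0.95, 0.9, 0.75, 0.5} in the full-scale protocol) is applied to every
spatial element of each layer's input.  The mask is indexed by the spatial
axes only (shared across channels) and redrawn per example per forward
pass, at train and test time alike; no inverted-dropout rescaling is
applied, so the test-time Monte-Carlo ensemble samples the same
distribution that was trained.  Regularization is the same L2 penalty as
MAP (the Gaussian-mixture approximation of the dropout KL).

**Spike-and-slab dropout (SSD).**  Each filter f has a learned inclusion
gate: a concrete (relaxed Bernoulli) variable

    b_f = sigmoid((logit(p_f) + logit(u)) / t),   u ~ Unif(0,1),

with temperature t = 0.02, which converges in distribution to
Bernoulli(p_f) as t -> 0.  Each weight has a Gaussian posterior
N(mu, sigma^2) with both parameters learned.  Sampling uses the local
reparameterization trick: because a sum of independent Gaussians is
Gaussian, the pre-activation at voxel v is drawn directly from

    N( sum_t mu_t h_{v-lt},  sum_t sigma_t^2 h^2_{v-lt} ),

i.e. one mean convolution of h and one variance convolution of h^2, then
`z = b_f * (mu* + sigma* eps) + bias`.  This gives one weight sample per
mini-batch example at convolution cost rather than weight-tensor cost.

The prior is spike-and-slab with p_prior = 0.5 (maximum-entropy gate),
mu_prior = 0, sigma_prior = 0.1.  The KL term factorizes over filters and
taps into a Bernoulli KL per gate plus a Gaussian KL per weight, both in
closed form.

### Parameterization and initialization

- sigma = softplus(rho): positivity holds by construction, no clipping.
  rho is initialized so sigma ~= 0.05 (half the prior scale — early
  training stays near the deterministic regime).
- p_f is stored as a logit, initialized at logit(0.9) (gates mostly open).
- mu uses fan-in-scaled Gaussian init, `sd = sqrt(2 / (C_in * 27))`.
- Biases are deterministic (one per filter, no posterior, excluded from
  the KL); the output-layer bias is initialized to the empirical class
  log-priors of the training labels.  This removes the long initial phase
  in which an imbalanced segmentation task is spent learning base rates
  and is particularly important for short CPU-scale schedules.
- Optional MAP warm start (``fit(warm_start_steps=...)``): a point-estimate
  network is trained first and its weights seed the variational means
  (the usual "posterior means from a pretrained point estimate"
  initialization for variational networks).  The variational objective is
  then optimized as usual; gates and weight scales adapt during the main
  run.  This shortens convergence considerably because the spike-and-slab
  sampler must otherwise learn the task and dropout-robustness
  simultaneously from a random start.
- Uniform draws for the concrete gate are clamped to [1e-7, 1 - 1e-7]
  (the log terms diverge at the endpoints); the pre-activation SD uses
  `sqrt(var + 1e-12)` to keep the noise path differentiable where a
  ReLU-dead input patch makes the variance exactly zero.

## Objective and optimization

The stochastic variants maximize the mini-batch evidence lower bound
(stochastic gradient variational Bayes): for a batch of M of N training
tiles,

    loss = (N/M) * sum_m [ -log p(y_m | x_m, w_m) ] + KL(q || prior),

with one weight/gate/mask sample per example and the KL (or the L2 penalty
for MAP/BD) added once per update at full weight.  Optimization uses Adam
(full-scale default: learning rate 1e-4, mini-batch 32 sub-volumes).  An
optional linear KL warm-up is available but off by default.  All gradients
are computed by hand-derived backpropagation through the sampling path
(including the concrete gate and the variance convolution) and are
verified against finite differences in the test suite.

Model selection tracks validation mean Dice at a configurable interval and
restores the best parameters at the end of training.  A non-finite loss
aborts with a diagnostic rather than continuing silently.

## Prediction and uncertainty

Prediction marginalizes the weight posterior by Monte Carlo: n_mc
stochastic forward passes per tile (default 10), averaged in probability
space — not in logits — and stitched to the full volume.  Fresh
weight/gate noise is drawn per tile and per pass.  The per-voxel
uncertainty is the entropy of the averaged softmax (natural log, in
[0, log C]; `0 log 0 = 0`).  Argmax ties break toward the lowest class
index.  The volume-level uncertainty is the mean entropy over voxels not
*predicted* as background; an all-background prediction raises an explicit
error instead of returning a meaningless summary.

## Evaluation

- **Dice** per class: `2 TP / (2 TP + FN + FP)`.  Defined-empty
  convention: a class absent from both prediction and target scores 1,
  absent from exactly one scores 0 (the ratio is 0/0 there; the choice is
  isolated in one function).  Mean Dice is the unweighted average over all
  C classes including background.
- **Voxelwise error prediction**: ROC/AUC of entropy as a ranking score
  for misclassified voxels (positives), restricted to voxels where either
  prediction or target is non-background — without that mask the huge
  mutual-background sea dominates the analysis.  Ties are handled by
  midranks.  Per-volume curves can be averaged on a common
  false-positive-rate grid, keeping per-volume AUCs for paired tests.
- **QC prediction**: manual ratings run 1 (best) to 4 (worst) from two
  raters (a third when the first two differ by more than 1); the
  consolidated score is the rater mean and a scan is "bad quality" iff
  that score is strictly greater than 2.  The ROC uses volume-level
  uncertainty as the score and bad quality as the positive class.
- **Statistics**: paired two-sided t-test on per-volume metrics
  (zero-variance differences raise an explicit degenerate-case error);
  and a paired bootstrap comparison of two scoring methods' QC AUCs —
  volumes resampled with replacement, the same index draw applied to both
  score vectors, 10,000 replicates by default.  The reported p-value is
  one-sided in the direction asserted by the full-sample point estimate,
  with tied replicates counted 1/2, so comparing a score vector against
  itself yields p = 0.5 exactly.  Degenerate replicates (one class after
  resampling) are redrawn under a hard cap.

## Synthetic phantoms

Real training corpora (thousands of scans with reference segmentations)
are not redistributable, so the package generates labelled phantoms with
known ground truth:

- **Geometry**: concentric ellipsoids (anisotropic semi-axes 0.45/0.40/
  0.35 of the edge) subdivided by octant planes; (shell, octant) cells map
  cyclically onto foreground classes, so even small phantoms host many
  spatially contiguous regions, loosely mimicking nested cortical/
  subcortical topology.  Every class id is guaranteed present.
- **Intensities**: per-class means evenly spaced over [20, 235] (the
  conformed 0-255 intensity range, background dimmest) plus additive
  Gaussian noise with SD 8 — about a quarter of the inter-class spacing,
  a clearly separable but non-trivial contrast.
- **Bias field**: multiplicative `1 + a * (sum of 3 random low-order
  cosine modes)`, default amplitude a = 0.05, i.e. a mild +-5% residual
  inhomogeneity of the kind left after modern scanner pre-correction.
- **Degradation** ("bad-quality" mode): severity-scaled artifacts —
  noise bursts in a random slab, motion-like directional blur, ringing
  stripes, intensity clipping.  Severity 0 is the identity and mean
  absolute change grows with severity.  No public description exists of
  what physically distinguishes low-QC scans in the motivating datasets;
  these artifact kinds are a modelling choice.

Everything is a pure function of its spec (seed included): identical specs
give bit-identical volumes; per-volume seeds in a dataset derive
deterministically from the template seed, as does the train/val/test
partition (floor(n * fraction) with the remainder assigned to training —
e.g. 11,480 volumes at 80-10-10 give 9,184/1,148/1,148).

What the phantoms do **not** emulate: real anatomy and its inter-subject
variability, MR acquisition physics (partial volume, Rician noise,
susceptibility), registration/orientation variation, and label noise in
the reference segmentations.  Passing the phantom-based suites therefore
demonstrates that the machinery — variational layers, ELBO training, MC
prediction, uncertainty-based error and QC detection — behaves as designed
on data of known structure; it does not certify segmentation accuracy on
clinical MRI.

## Desk-scale experiment sizes

The acceptance experiments run the full pipeline at sizes chosen for a
single CPU: 20 phantoms of 64^3 voxels with 8 classes (16/2/2 split), a
16-filter network, training on 16^3 sub-crops of the training volumes
(the network is fully convolutional; the 32^3 tiling remains the
inference contract) with mini-batches of 16 at learning rate 3e-3 — a
200-step MAP warm start followed by 200-240 spike-and-slab steps with a
60-step KL warm-up (the full-scale 1e-4/32-subvolume defaults remain the
library defaults) — then 10 MC samples for held-out prediction and
reduced MC counts for the volume-level QC sweep.  These sizes are the
package's own desk-scale protocol; the statistical behaviour they probe
(learnability, uncertainty-error association, clean/degraded separation,
test calibration) is size-robust.

## Known limitations

- Tile-border voxels see zero padding inside a 37^3 receptive field; the
  pipeline inherits this from the non-overlapping tiling design.
- Per-tile weight sampling during MC prediction means different tiles of
  one volume see different weight samples within one pass.
- The BD mask is shared across channels (the mask is indexed by spatial
  position only); per-channel masking is a plausible alternative reading.
- The conform step approximates the observable contract of the standard
  conform operation (1 mm isotropic 256^3, 0-255 intensities), not its
  exact histogram-based intensity normalization.
- Gates are per-filter; per-weight gates, learned temperatures, and
  full-covariance posteriors are out of scope.
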