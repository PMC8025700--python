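# Methods

This note records the model as implemented, the defaults and why they are
set where they are, what the synthetic data does and does not emulate, and
the numerical choices a maintainer would otherwise have to reverse-engineer.

## Model

The segmenter maps a cloud `P ∈ R^{M×3}` to per-point logits over
`N = 2` classes (non-ear = 1, ear = 2).  Four properties drive the design:
permutation invariance (point order must not matter), transformation
robustness (rigid transforms and scale must not change labels), locality
through point-to-point distance, and resolution robustness.

**Decomposition.** A seeded uniform permutation cut into `L` near-equal
chunks partitions the point indices; the disjointness and coverage
identities hold exactly, and each subset is an unbiased subsample, so
subset covariance matches the cloud's in expectation (tested).  Inside the
forward pass the seeded partition is attached to *canonical lexicographic
ranks* of the coordinates rather than raw row indices; this is what makes
the whole network permutation-equivariant exactly rather than only in
distribution.  Remainder points go to the first subsets; indices are kept
ascending per subset so tie-breaking is stable.

**Edge features and pattern blocks.** Per subset, each point's K nearest
neighbors are found in the *current* feature space before each of the four
blocks (dynamic graph).  Neighbors are sorted by distance; ties break by
lexicographic feature rows and then canonical order, so duplicated points
and permuted inputs give identical neighbor multisets.  The block applies
two dense (1×1-conv) layers with batch normalization and leaky-ReLU
(slope 0.2) to each `(f_q, f_i − f_q)` row and max-pools over K.  Widths
are {32, 32, 32, 32} (half that in the light variant), giving a 128-long
(64 in light) concatenated per-point feature.

**Descriptor linkage.** `ψ_l` = feature-wise max over subset `l`; `φ` =
feature-wise max over all points followed by one dense + leaky-ReLU layer
of the same width.  The linkage coefficients `ω = Ψ⁺φ` are computed by
SVD pseudo-inverse with `rcond = 1e-10`; the loss adds
`λ · σ(ω)` (population standard deviation, `λ = 10 000`).  When every
`ψ_l` equals `φ` the coefficients are equal and the penalty vanishes.

**Decoder.** Each point's `(feature ⊕ ψ_l of its level ⊕ φ)` (384-wide
by default) passes through dense layers {256, 256} with BN, leaky-ReLU and
dropout 2/3 (training only), then a dense layer to `N` logits.

**Loss.** Weighted mean cross-entropy over the cloud's points with dynamic
weights `Ω_k = |C_k − n_k/M|`, `C = (0.95, 1.0)`; probabilities are
clipped at 1e-12 before the log.  With ears a small minority, `Ω_ear` is
large and `Ω_non-ear` small, rebalancing the gradient.

## Gradients and optimization

All gradients are computed by hand-written backpropagation in NumPy and
verified against central finite differences at 1e-4 relative tolerance
(network weights, BN parameters, and the descriptor pathway).  Three
deliberate choices:

* **Fixed-ω mapping gradient.**  `σ(ω)` is differentiated with the
  pseudo-inverse held fixed, using the first-order least-squares relation
  `δω ≈ Ψ⁺(δφ − δΨ ω)`.  The exact derivative has an extra residual term
  (through `(ΨᵀΨ)⁻¹ δΨᵀ r`); dropping it avoids differentiating the SVD
  and is stable.  Finite-difference checks of the *network* therefore run
  with `λ = 0`; the approximation is intentional and documented, not a
  bug.
* **KNN indices and max-pool argmaxes are constants** during the backward
  pass, as is standard for dynamic-graph edge convolutions.
* **BN statistics.**  Train mode uses batch statistics with full backprop
  through them; running averages (momentum 0.9, eps 1e-5) serve eval mode.
  The global-descriptor MLP carries no BN: it sees one pooled vector per
  cloud, so batch statistics would be degenerate at that granularity.

Training: Adam (β₁ 0.9, β₂ 0.999), lr decaying exponentially from 1e-3 to
a floor of 1e-4 across the configured epochs, batch size 10 (gradients
averaged over the batch's clouds), rotation about +z ∈ [0, 2π), scale
∈ [0.8, 1.25], translation ∈ [−0.1, 0.1] per axis.  Rotation is restricted
to the vertical axis because plants are upright and acquisition is
turntable-like; full 3D rotation would destroy the gravity cue that makes
"ears sit on top" learnable.  The partition seed is refreshed each epoch
(extra regularization; the decomposition is random by design) and fixed at
inference for determinism.  The checkpoint kept is the best validation
mIoU.  All randomness derives from one training seed; two identical runs
produce bit-identical histories.

`K` defaults to 20 (8 in the desk-scale experiment); the subset size must
exceed `K` or the configuration is rejected.  Clouds are centered at their
centroid and scaled into the unit sphere before the network sees them; the
normalization record converts phenotype lengths back to original units.

## Phenotyping

Ear instances are connected components of the graph joining predicted-ear
points within radius `eps` (single linkage), discarding components smaller
than `m_min = 10` points.  Two refinements over a fixed radius:

* **Adaptive radius.**  `eps` defaults to 2× the median distance to the
  3rd nearest neighbor among ear-labeled points.  Single-linkage keeps a
  cluster connected when the radius exceeds its largest within-cluster
  nearest-neighbor gap (≈ 2.5–3× the typical spacing); the median-based
  estimate tracks point density across resolutions and, unlike an upper
  quantile, is not inflated by scattered false-positive points.  A factor
  scan showed a wide plateau (≈ 1.8–2.5) over clean, noisy, downsampled
  and model-predicted inputs; 2.0 is its center.  A fixed `eps` can still
  be passed.
* **Fragment reattachment.**  Dropped sub-`m_min` components within
  2×eps of a retained instance are merged into the nearest one.  This
  cannot change the count, but prevents an isolated tip point from
  truncating a length measurement.

Ear length is the max-minus-min extent of the instance's points along
their first principal axis (SVD of centered coordinates) — a robust proxy
at 20–200 points per ear; geodesic length is out of scope.  Plant height
is the vertical (+z) extent of the whole cloud; relative ear length is
mean ear length over plant height.

## Synthetic data

The generator emulates what multi-view photogrammetry of a pot-grown
wheat plant yields: surface samples of a slightly curved stem, a few
drooping ribbon leaves, and 0–8 ears, each an *area-uniform* sample of an
ellipsoid surface (major axis 1.5, radial spread 0.25, in units where the
stem is 10 tall) atop its own tiller; Gaussian coordinate noise
(sd = 2 % of stem height) and 1 % uniform-box outliers are added, and the
cloud is truncated/padded to exactly `M` points.  Ears sit on a ring of
radius 0.25× stem height with tiller heights alternating ±0.10× stem
height, so ear centers are far more separated than the guaranteed minimum
(3× radial spread) — matching the open canopy of a real multi-tiller
plant and making the instances recoverable by single linkage at every
count in 0–8, which is verified with oracle labels on noisy and clean
plants.

Point budget: each ear receives `min(8 %, 32 %/n_ears)` of the points, so
the ear class is a minority (≈ 5–32 %) at every count — the regime the
dynamic class weights are for; the rest splits among stem (≈ half),
leaves and tillers.  Ground-truth ear lengths are the *realized* extents
of the emitted noisy ear points along each nominal axis (consistent with
the emitted cloud); the nominal major axis is recorded in the dataset
manifest.

What the generator does **not** emulate: photogrammetric artifacts beyond
isotropic noise and box outliers (holes, ghost surfaces, density falloff
with occlusion), awn/spikelet microstructure, leaf curl, and inter-plant
variety differences.  Passing the synthetic recovery tests therefore
demonstrates that the architecture, loss, training loop and phenotype
extraction work end to end on clouds with the right topology and class
imbalance — not that the reported accuracies transfer to real
reconstructions.

## Desk-scale reference experiment

The test suite and `scripts/acceptance.py` train the light configuration
(widths {16, 16, 16, 16}, `L = 4`, `K = 8`) on 40 synthetic plants of 512
points for 30 epochs — sizes chosen so the whole experiment runs in
minutes on one CPU while leaving every mechanism (imbalance weighting,
descriptor linkage, augmentation, adaptive clustering) active.  Three
seeds are trained and the median held-out accuracy reported; the counting
pipeline runs on 20 fresh plants spanning 0–8 ears.  Typical results:
held-out mean accuracy 85–92 %, count R² 0.94–0.99, RRMSE 0.27–0.75,
mean absolute count error ≈ 1; oracle-label recovery is exact with mean
length error well under 1 %.

## Numerical details and edge cases

* Coordinates are float64 internally; PLY files are written as float32
  (standard dialect), hence the 1e-6 round-trip tolerance.
* A single-point cloud normalizes to the origin with scale 1; a cloud
  with zero vertical extent is rejected by phenotyping.
* `resample_to_count` draws without replacement when downsampling, with
  replacement when upsampling; same seed, same result, bit for bit.
* RRMSE excludes pairs whose true count is zero (the relative error is
  undefined there) and reports how many were excluded; zero-ear plants do
  occur by design.
* A class absent from both truth and prediction contributes IoU 1, so
  mIoU stays defined on clouds lacking a class; segmentation metrics are
  averaged per cloud, then over clouds.
* Pearson R² is the square of the standard correlation coefficient
  (scale-invariant); a constant series is rejected rather than silently
  returning 0/0.
* Non-finite training loss aborts immediately, naming the epoch.

## Known limitations

* The mapping-loss gradient is first-order (see above); with very
  ill-conditioned `Ψ` the penalty's descent direction can be inaccurate.
* Parameter totals depend on choices the architecture only fixes up to
  the descriptor stage (`count_parameters` reports the exact count for
  any configuration; the default configuration has 193 602 trainable
  scalars, the light one 123 938).
* Ear length via principal-axis extent underestimates strongly curved
  ears and inflates under heavy noise; the generator's truth accounts for
  noise but not curvature because generated ears are straight.
* Single-linkage clustering assumes ears do not touch; physically
  contacting ears would merge.
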