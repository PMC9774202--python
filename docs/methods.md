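# Methods

`fedprune` is a desk-scale, single-process simulator for personalized
federated learning across heterogeneous edge clients.  The pipeline it
models comes from precision poultry farming — classifying the day-age
(1–100 days) of chickens from images collected by many low-power devices in
rearing houses — but every component is generic: a synthetic data generator
with the statistical structure of such datasets, a small architecture IR
with four CNN families and a lightweighting rewriter, data-directed
structured filter pruning under per-client resource budgets, and a
scaling-based aggregation rule for partially overlapping submodels.

## The federated model

One communication round, with `K` clients holding disjoint shards:

1. **Importance learning (client side).**  Each client attaches a trainable
   multiplicative gate `g ∈ R^F` (initialized at 1) to every prunable
   channel group of the global model and minimizes
   `CE(data) + λ·‖g‖₁` over its local shard with the backbone weights
   frozen (λ = 1e-4, gate step 0.05).  The final gate magnitudes are the
   per-filter importance scores.  Because the loss term is computed on local
   data, the scores encode the client's data distribution: filters useless
   for the local task receive no gradient support and are shrunk by the L1
   penalty.  A filter whose output is identically zero receives exactly zero
   loss gradient under batch norm (its normalized output is 0 and beta
   stays 0), so only the penalty moves its gate — the property the unit
   tests verify on a two-filter toy network.
2. **Budgeted pruning.**  The client's pruning rate is the smallest rate on
   a 0.05 grid whose analytically counted parameters/MACs fit the client's
   budget; the rate is uniform across prunable groups.  Per group,
   `ceil((1-rate)·F)` filters of highest importance are retained (ties to
   the lower index), and all downstream consumers are sliced consistently.
   The classifier head, the input, and depthwise filters are exempt;
   channel sets shared across residual merge points are pruned jointly
   (one retained-index set per *channel group*, not per layer).
3. **Local training.**  Mini-batch SGD with momentum 0.9 on the submodel,
   initialized from the global parameter slices.  Local work is measured in
   optimizer steps per round (not epochs): every device contributes a fixed
   amount of computation per round, so adding clients adds training effort,
   as added edge devices would.
4. **Scaling-based aggregation (server side).**  Each scalar coordinate is
   updated to the weighted mean over the clients that retain it, with
   weight `w_k = n_k · (1 + rate_k)`; coordinates retained by nobody keep
   their previous value.  The `(1 + rate)` factor compensates heavily
   pruned clients' reduced coverage; at rate 0 the rule is exactly
   sample-count-weighted FedAvg.  Weights are normalized per coordinate
   before summation, which makes a single-holder coordinate take the
   holder's value bit-exactly — and makes a 1-client unpruned federation
   bit-identical to centralized training, a collapse property the tests
   assert.
5. **Similarity-based submodel tuning.**  Client similarity is the cosine
   of the concatenated, per-group L2-normalized importance vectors.
   Clients are grouped by single linkage at threshold τ (default 0.9);
   within a group, a sample-count-weighted mean importance re-selects each
   member's retained indices at its own rate, so similar clients converge
   to nested masks while dissimilar clients keep individualized masks.  An
   adjustment that would violate a member's budget falls back to that
   member's original mask.

Importance (and hence masks) is refreshed on a period (default every 10
rounds, i.e. once at round 1 for short runs); communication is in-process,
with upload volume reported analytically at 4 bytes per transmitted
parameter.

## Backbones and lightweighting

Four small families (`alexnet_s`, `vgg_s`, `googlenet_s`, `resnet_s`) are
expressed in a block IR: 2–4 conv stages, batch norm after every
convolution, global average pooling, one dense head; ≤ 1M parameters at
width multiplier 1.0.  They are deliberately desk-scale stand-ins — the
object of study is the federated pruning framework, not ImageNet capacity.

The lightweighting pass rewrites a spec in four ways:

- **Depthwise separable convolution:** every standard Dk×Dk conv (Dk>1)
  becomes depthwise + pointwise.  The MAC ratio to the standard conv is
  `1/N + 1/Dk²`; for 3×3 kernels and a few hundred filters this is an
  8–9× reduction.
- **Linear bottlenecks:** the low-dimensional 1×1 projection outputs carry
  no nonlinearity (identity activation), avoiding ReLU information loss in
  low dimensions; ReLU is used elsewhere.
- **Inverted residuals:** residual blocks become expand (t=6) → 3×3
  depthwise → linear 1×1 projection, with the identity skip present at
  stride 1 and matching widths.
- **Head redesign:** a pointwise feature-generation conv sitting before
  global average pooling is moved after it, so it runs at 1×1 instead of
  e.g. 7×7 spatial resolution (49× fewer MACs for that layer); a pointwise
  projection conv immediately preceding it is dropped.

Costs are counted analytically in multiply-accumulates (conv and dense
only; batch norm, pooling and additions are not counted) and parameters
(batch-norm gamma/beta included; convolutions carry no additive bias —
beta is the offset — which also keeps both cost measures linear in the
retained-filter count, MACs exactly so).

## The NumPy engine

Training and inference run on a small NumPy engine written against the
execution plan: standard/pointwise convolution in a kernel-offset matmul
formulation, depthwise convolution, batch norm, ReLU, non-overlapping max
pooling, global average pooling, dense, residual addition, channel
concatenation.  Gradients are hand-derived and verified against finite
differences in the test suite.  Everything is float64.

Batch norm always normalizes with the statistics of the *current batch*; no
running averages are kept.  Consequences, all deliberate:

- the trainable parameter set equals exactly the set the server aggregates
  (no stateful buffers to reconcile across clients);
- zero-learning-rate or zero-epoch training is a bit-exact no-op;
- the structural-equivalence oracle (pruned submodel ≡ full model with the
  complementary slices zeroed) holds to machine precision;
- evaluation must use moderately sized, class-mixed batches: `predict`
  processes samples in a fixed seeded permutation (evaluation sets are
  often class-sorted, and class-homogeneous batches would shift the
  normalization statistics) and returns predictions in input order.

## Synthetic day-age data

The generator draws, per image, a bright disc (intensity 0.85 on a 0.15
background) whose radius is strictly monotone in the day-age label —
`r = 2 + (0.38·min(H,W) − 2)·label/100` pixels — with ±2 px center jitter
and i.i.d. Gaussian pixel noise σ = 0.1, clipped to [0, 1].  Monotone size
mirrors how morphology scales with age and makes difficulty tunable via σ.
The class-distribution preset reproduces the emulated dataset's published
per-day counts: 78 present classes, counts 249–3176, whole missing spans
(days 32–34, 51–67, 76, 91).  Absent classes are dropped from the label
space by contiguous re-indexing with a stored label map.

What the generator does *not* emulate: real chicken morphology, texture,
lighting, occlusion, camera variation, or label noise.  Passing tests
therefore demonstrate that the framework's mechanics (pruning, aggregation,
personalization, lightweighting) behave correctly and that its relative
trends hold on a learnable imbalanced task — not that any particular
absolute accuracy transfers to real imagery.

Rebalancing augments every class up to a target count with geometric
transformations (flip, rotate, crop, deform, scale), color transformations
(noise, blur, color shift, erase, fill), and two-sample mixes
(SamplePairing-style pixel averaging, or SMOTE-like convex combinations),
keeping all originals.  The train/test split is stratified 7:3 per class
(test count floored, remainder to train).  Client partitioning assigns each
client a ratio-proportional share of every class, with seeded randomized
remainder assignment.

## The desk-scale benchmark

The standard benchmark used by the heavier tests: 10 evenly spaced day-age
classes, 200 images per class at 32×32×3, stratified 7:3 split, and the
lightened `alexnet_s` at width 0.5 (the model an edge client would deploy);
5 rounds × 16 local steps, SGD momentum 0.9, batch 48, lr 0.2 decayed ×0.6
per round.  The optimization story behind those choices: the task is
near-perfectly separable but essentially ordinal along one size feature,
so a constant learning rate oscillates between adjacent-class boundaries —
per-round decay stabilizes the endpoint; and the post-pooling
batch-normalized feature layer of the lightened `alexnet_s` rescales the
compressed size feature to O(1), which conditions the classifier head well.
Problem sizes (rounds, steps, widths) are the package's own desk-scale
choice so that a full client-count sweep stays tractable on one CPU.

## Numerical and design notes

- All randomness flows through explicit integer seeds via
  `numpy.random.SeedSequence`; identical configuration ⇒ identical results,
  end to end, including batch order.
- Tie-breaks: filter retention prefers the lower index at equal importance
  (stable argsort on negated scores).
- Pruning-rate grid step 0.05; an unattainable budget (below the
  one-filter-per-group submodel) is an error, not a silent clamp.
- Macro averaging for multiclass precision/recall; classes with undefined
  per-class terms (never predicted / no true samples) are excluded from the
  macro mean and logged, not zero-filled.
- Degenerate inputs: empty datasets, empty shards, single-sample classes in
  a stratified split, zero-norm importance vectors, and budget-violating
  tuned masks all raise or fall back explicitly.

## Known limitations

- No real image ingestion beyond a simple PNG directory layout; no
  camera-resolution processing.
- Communication is simulated in-process; no transport, encryption, secure
  aggregation, or straggler modelling.
- Uniform per-client pruning rate (per-layer-adaptive rates are a natural
  extension point of `make_mask`).
- Batch-stat batch norm means single-sample inference is ill-defined;
  evaluate in batches.
- Wall-clock latency is out of scope; the resource report is analytic
  (params, MACs, transfer bytes).
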