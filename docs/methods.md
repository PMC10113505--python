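# Methods

## Overview

`sparrowtune` optimizes the training hyperparameters of a convolutional
image classifier with the sparrow search algorithm (SpaSA).  A candidate
is a vector in `[0, 1]^15`; a decoder maps it to a concrete training
configuration; the fitness of a candidate is the validation accuracy of a
classifier trained under that configuration for a small, fixed number of
epochs.  Around this core sit an image pipeline (resize, scaling,
augmentation, class balancing, splitting), a pooled one-vs-rest metric
suite, and a two-stage diagnosis cascade for the kidney application the
toolkit was designed around: CT triage into Cyst / Normal / Stone / Tumor,
with tumor cases routed to histopathology grading (Grade 0–4, the
clear-cell renal cell carcinoma convention).

## The optimizer

Population of `N` solutions, `T_max` iterations.  Each iteration
evaluates every solution, sorts best-first (stable sort; ties keep their
original order), snapshots the best, worst and best-producer positions,
then applies three updates in order.

**Producers** — the top `PD = max(1, round(producer_ratio · N))` rows.
One alarm value `R₂ ~ U[0,1]` is drawn per update call (the per-call
rather than per-sparrow convention was an open choice; per-call matches
the flock-level interpretation of the alarm).  If `R₂ < ST`, row `i`
decays by `exp(−t/(α_i · T_max))` with its own `α_i ~ U(0,1]`; otherwise
it takes an independent standard-normal step per coordinate (`Q` is drawn
per element, since the ones-row `L` it multiplies acts element-wise).

**Scroungers** — the remaining `N − PD` rows, indexed by their population
position `i` (1-based).  For `i > N/2`:
`X ← Q ⊙ exp((X_worst − X)/i²)`.  Note the literal form replaces the
position with a Q-scaled value near `exp(·) ≈ 1`, i.e. a near-standard
normal draw clamped to the cube — it is a strong randomization, kept as
written; users should know these followers effectively restart.  For
`i ≤ N/2`: `X ← X_P + |X − X_P| ⊙ A/D` element-wise with
`A ∈ {−1,+1}^D`.  The pseudo-inverse `A⁺ = Aᵀ(A·Aᵀ)⁻¹` collapses to
`Aᵀ/D` exactly because `A·Aᵀ = D`; we implement that closed form,
applied per coordinate (the strict matrix product `|X−X_P|·A⁺·L` would
add one shared scalar to every coordinate, which destroys per-dimension
search; the element-wise reading is the established one in SpaSA
implementations).

The published pseudocode indexes followers `1..N−PD`, which read
literally would re-update the producers; we update the non-producer rows
and use the population position in both the branch condition and the `i²`
divisor, matching the equations' intent.

**Scouts** — `SD = max(1, round(scout_ratio · N))` rows drawn uniformly
without replacement.  A scout whose fitness differs from the best moves
`X ← X_best + β·|X − X_best|` with scalar `β ~ N(0,1)`; a scout at the
best fitness moves `X ← X + K·|X − X_worst|/((f_i − f_w) + ε)` with
`K ~ U[−1,1]` and `ε = 1e−50` guarding the flat-population division (in
that degenerate case the clamp to `[0,1]` dominates, which is the
intended escape behaviour).

All randomness consumed by one update call is collected in an explicit
`UpdateRandoms` record, so the update equations are deterministic
functions that the test suite compares against an independently written
literal transcription.  Positions are hard-clamped to `[0,1]` after every
update — the codec's domain requires it.  Defaults: `N = 10`,
`T_max = 10`, `producer_ratio = 0.20`, `scout_ratio = 0.20` (the scout
fraction is not pinned by the source convention; 10–20 % is the common
choice and it is configurable), `ST = 0.8` within its `[0.5, 1]` band.
Fitness is evaluated once per solution per iteration with no caching
(solutions mutate every iteration), so a run costs exactly `N·T_max`
evaluations; the reported history is the best-ever trace and is monotone
by construction.  Optimizer state (population, scores, RNG state,
iteration) serializes to JSON, and a resumed run reproduces the
uninterrupted one bit for bit.

## The encoding

Fifteen ordered dimensions: loss, batch size, dropout, fine-tune ratio,
optimizer, scaler, augmentation flag, then eight augmentation magnitudes
(rotation, width/height shift, shear, zoom, horizontal/vertical flip,
brightness).  Discrete dimensions with `n` choices decode by
`floor(v·n)` clamped to `n−1` at `v = 1` — so `v = 0.85` against the
12-value batch grid `4, 8, …, 48` selects index 11, batch 44.  Continuous
dimensions interpolate linearly; booleans threshold at 0.5.  Ranges:
batch 4–48 step 4; dropout `[0, 0.6]`; fine-tune ratio 1–100 (integer
percent); six losses (categorical cross-entropy, categorical hinge, KL
divergence, Poisson, squared hinge, hinge); eleven optimizers (Adam,
NAdam, AdaGrad, AdaDelta, AdaMax, RMSProp, SGD, FTRL, SGD-Nesterov,
centered RMSProp, AMSGrad-Adam); four scalers; rotation 0–45°,
shift/shear/zoom `[0, 0.25]`, brightness centre `[0.5, 2.0]`.

Two open semantics were fixed as follows.  *Brightness*: one coordinate
cannot express an arbitrary interval, so it decodes to a centre `c` and
the emitted range is `[max(0.5, c−0.3), min(2.0, c+0.3)]` (half-width
configurable as `codec.BRIGHTNESS_HALF_WIDTH`); published configuration
tables show intervals of varying width, so this is a documented
stand-in.  *Fine-tune ratio*: interpreted as the percentage of backbone
blocks, counted from the output end, left trainable —
`ceil(ratio/100 · n_blocks)` blocks unfrozen, ratio 0 freezing the whole
backbone, head always trainable.  Trainable-parameter count is therefore
non-decreasing in the ratio.

The optimizer always operates on the fixed 15-dimension space; when the
augmentation flag decodes to false the trailing eight coordinates are
carried but ignored.  The reduced 7-dimension variant is the projection
onto the first seven coordinates (`SearchSpace(reduced=True)`).

## The image pipeline

Images are floats in `[0, 255]`, shape `(H, W, 3)`, resized by bicubic
resampling (Pillow, float channels — constants survive exactly) to a
common side (128 for real data; the synthetic fixtures default to 32 to
keep tests fast).  Four per-image scalings: `X/max(X)`, standardization,
min-max, max-abs; statistics are per image, not per dataset, because the
scaler is applied identically at train and predict time without fitted
state.  Flat images fall back to zeros with a warning.

Augmentation draws rotation, shifts, shear and zoom uniformly from
symmetric intervals, applies the combined centre-anchored affine map with
reflect padding and bilinear interpolation, flips with probability 0.5
where enabled, multiplies by a brightness factor drawn from the range,
and clips to `[0, 255]`.  Draw order is fixed regardless of magnitudes so
seeded reproducibility survives configuration changes.

Class balancing is up-sampling only: every class is raised to the largest
class's size by appending augmented copies of uniformly resampled class
members; originals are never modified or removed.  On the 4-class CT
sizes (3,709 / 5,077 / 1,377 / 2,283) this yields 5,077 per class,
20,308 total; on the 5-class grading sizes (45/45/60/67/60) it yields 67
per class, 335 total — the originally printed total of 355 for that set
is inconsistent with its own per-class figure (5 × 67 = 335), and the rule's
result is what the package produces.  The default balancing augmentation
uses moderate magnitudes (rotation 20°, shifts/shear/zoom 0.1, both
flips, brightness 0.8–1.2), i.e. the middle of the search ranges.

Splitting is stratified per class (test count = `round((1−r)·n_class)`,
within one image of the global ratio), default 85 % train+validation /
15 % test with 15 % of the training share carved off for validation (the
source convention gives no validation fraction; 15 % is the package
default and configurable).  In orchestrated runs balancing happens before
splitting, so the split is *grouped by source image*: an augmented copy
always lands in the same partition as its original, preventing leakage of
near-duplicates into validation or test.  Grouped assignment trades exact
per-class counts (they can drift by one group) for leak-freedom; an
ungrouped mode exists for strict count fidelity.

## Fitness evaluation

A fitness call decodes the solution, builds the classifier (backbone conv
blocks + dropout over pooled features + softmax head), trains for 5
epochs by default (2 in the desk-scale tests) with the decoded batch
size, loss, optimizer and — when enabled — on-the-fly augmentation, and
returns accuracy on the validation partition (`holdout` mode, the
default).  A `whole-dataset` mode that scores train+validation together
is provided for comparability with conventions that evaluate on
everything, but it mixes training data into the fitness and the mode used
is always recorded on the result.  A non-finite training loss is caught
and reported as fitness 0 with a `diverged` flag rather than raised, so
the optimizer survives pathological loss/optimizer pairings.  Fitness is
total over the decode domain.

The trainable unit is a compact CPU neural-network engine written on
numpy: 3×3 same-padding convolutions (He init), ReLU, 2×2 max pooling
(tie-splitting backward; a no-op below 2×2 spatial size), global average
pooling, inverted dropout, dense layers; softmax with the six losses
defined on probabilities and chained through the softmax Jacobian
(backward passes are finite-difference-checked in the tests); the eleven
optimizers with their conventional defaults (Adam family lr 1e−3, SGD
1e−2, FTRL-proximal with power −0.5 schedule).  The reference backbone
`surrogate-tiny` is three conv blocks of widths 16/32/64 (~24 k
parameters), chosen so a fitness call on 32×32 fixtures takes well under
a second.  The familiar backbone names (VGG16 … NASNetMobile) construct
scaled-down randomly initialised sketches whose block counts echo the
namesakes' relative depths; pretrained weights are not bundled, so
requesting them warns and falls back to random initialisation.  These
named backbones are smoke-tested for construction and forward pass only.

## The cascade

`cascade_predict` routes one case through both stages: the CT model's
label is reported; `Tumor` cases are graded by the histopathology model
when a slide is supplied (otherwise flagged `grading pending`); `Normal`
needs no further grading; `Stone`/`Cyst` route to their own treatments.
Empirically on the synthetic fixtures, joint cascade accuracy stays
within 0.05 of the product of the stages' standalone accuracies (the
tests measure this).

## Metrics

Multiclass results pool one-vs-rest: each (sample, class) pair is one
binary outcome, so under argmax prediction the pooled counts satisfy
`TP+TN+FP+FN = n·C` and `ΣFP = ΣFN`.  Published confusion tables for
this problem show FP ≠ FN, which is impossible under pure argmax pooling;
a per-class threshold-0.5 mode (which can predict zero or several classes
per sample) is therefore also provided, and the aggregation mode is
always recorded.  From the pooled counts: accuracy, precision,
sensitivity, specificity, `F1 = 2TP/(2TP+FP+FN)`, `IoU = TP/(TP+FP+FN)`.
AUC is the macro one-vs-rest rank statistic (classes absent from the
truth are skipped; a single-class truth has no AUC) and cosine similarity
is the mean per-sample cosine between one-hot truth and the probability
row.  AUC/IoU/cosine are named but not defined in the source convention,
so these are the package's chosen definitions.  Zero-denominator metrics
are reported as absent, never as 0.  Percentages are rounded half-up at
two decimals for display only; full precision is kept internally.

## Synthetic fixtures

Each class renders as a deterministic unit-variance texture — an oriented
sinusoidal grating plus a smoothed random field whose granularity grades
with the class index — scaled by `signal_strength` and added to a flat
128 base with Gaussian pixel noise (`noise_sd`, default 8 on the 0–255
scale).  At signal 0 the class-conditional distributions coincide; at
signal 1 with low noise a held-out nearest-centroid classifier exceeds
0.99 accuracy, and separability is monotone in the signal.  The class
structures mirror the imbalanced 4-class CT and 5-class grading problems
(`FixtureSpec.four_class()` / `.five_class()` carry the real per-class
counts as defaults).  The textures are synthetic stand-ins: passing tests
demonstrates that the machinery (balancing, search, training, cascade)
behaves correctly on controllably separable data, not that any particular
accuracy transfers to real CT or histopathology images.

## Reproducibility and problem sizes

One run seed derives, via a seed sequence, independent sub-seeds for the
optimizer, the balancing pass, the split and the per-evaluation training
streams, so changing one component does not desynchronize the others, and
a repeated seed reproduces the whole run exactly.  The test suite runs
the optimizer oracle on 100 random instances, bound preservation on
1,000 fuzzed updates, benchmark dominance at D = 10 / N = 20 / T = 100
over 20 seeds, and the end-to-end search at N = 4, T = 3, 2 epochs on
32×32 fixtures with 5 paired seeds against an equal-budget random search
— sizes chosen so the whole suite completes in well under a minute of
optimizer time and a few minutes overall on one CPU.

## Known limitations

- The near-restart behaviour of the literal scrounger first branch (see
  above) makes half the followers explore aggressively; this is faithful
  to the published form but costs exploitation on smooth problems.
- Named backbones are depth sketches without pretrained weights; transfer
  learning proper (ImageNet features) is out of reach offline, so the
  fine-tune ratio exercises the freezing machinery rather than real
  feature reuse.
- Per-image scaling statistics make the scalers stateless but differ from
  dataset-level scalers fitted on train only.
- The brightness centre±width decode cannot reproduce arbitrary-width
  brightness intervals.
- Headline accuracies reported for the real Kaggle CT/histopathology
  datasets require those external datasets and GPU-scale training of full
  backbones; they are outside this package's test surface by design.
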