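# Methods

## Model and procedure

`twocell` performs supervised label transfer for scATAC-seq gene-score
matrices. The unit of analysis is a genes × cells matrix of non-negative
accessibility summaries; labels live on the reference cells only.

**Preprocessing.** Features are the top-`k` genes (default `k = 3000`) by
one-way ANOVA F-statistic of the log-normalized score across the reference
label groups. Normalization rescales each cell's scores over the selected
genes to a fixed total of 10,000 before `log1p`; standardization centers and
scales each gene using the population (1/n) standard deviation. The
F-statistic is computed on log-normalized scores by default so library-depth
differences between cells do not dominate the ranking (`ftest_space="raw"`
switches to raw scores). Constant genes have an undefined 0/0 F-ratio and
are assigned F = 0 (they must never be selected); genes whose within-group
variance is zero while group means differ separate the groups perfectly and
are clamped to the largest finite float so they rank first. Ties are broken
by input gene order, making selection deterministic.

**Round 1.** A multilayer perceptron — input dropout, two ReLU hidden layers
of 64 and 16 units, linear output, tempered-softmax head (T = 1) — is
trained with mini-batch Adam on cross-entropy against one-hot labels.
Dropout is applied to the input layer only: with a few thousand sparse,
standardized inputs that is where co-adaptation to individual genes happens.

**Anchors.** Prediction entropy (natural log; `0·log 0 := 0`, so one-hot
rows score exactly 0 and all values lie in `[0, log K]`) ranks target cells.
By default the `floor(0.4·M)` globally lowest-entropy cells become anchors;
a per-type quantile mode is available because anchor composition can
otherwise skew toward easy types. Ties at the boundary are broken by cell
index, for determinism. Pseudo-labels are the round-1 argmax. Minority
pseudo-types are oversampled with replacement up to the ceiling of the mean
per-type anchor count; the ceiling guarantees minority classes strictly gain
examples.

**Round 2.** A teacher MLP is trained on the (oversampled) anchors with
plain cross-entropy; its logits are softened at `T2 = 3` only when producing
the student's soft targets — the teacher itself is optimized at T = 1.
The student, of identical architecture, minimizes

    L = α·H(p, q_s^{T1}) + (1−α)·KL(q_t^{T2} ‖ q_s^{T2})

with `α = 0.1`, `T1 = 1`, 30 epochs. The KL term is *not* multiplied by the
classic `T2²` gradient-scale correction by default (`kd_t2_square=True`
restores it). Final calls merge round-1 labels for anchors with student
predictions for non-anchors. When anchors collapse to a single predicted
type the second round is skipped with a warning and round-1 labels are
returned.

## Design choices where the design was open

- **Independent standardization.** Reference and target are standardized
  each with their own per-gene statistics. The second round's premise is
  adapting to the target distribution; independent standardization already
  removes gross gene-wise location/scale shift. `standardize_with_ref_stats`
  applies reference statistics to the target instead.
- **One standardized space per dataset, not per subset.** Anchors and
  non-anchors are drawn from the same target batch, so round 2 trains and
  predicts in the whole-target standardized space. Re-standardizing the
  anchor subset separately was measured to cost several accuracy points:
  anchors are composition-biased toward confidently predicted types, so
  subset-level gene statistics differ systematically from those of the
  non-anchors the student must predict.
- **Warm-started second round.** Teacher and student initialize from the
  round-1 weights rather than from scratch. The anchor set is small
  (hundreds of cells at desk scale) and a from-scratch model memorizes it
  — training loss reaches ~1e-4 while non-anchor accuracy falls below
  round 1, inverting the method's purpose. Fine-tuning from the round-1
  solution keeps reference knowledge and makes the second round
  at-worst-neutral. `KDClassifier` used standalone still initializes
  freshly; only the pipeline passes `init_weights`.
- **Round-1 optimizer defaults** (unspecified upstream): Adam, learning
  rate 1e-3, batch 32, 50 epochs with early stopping on a training-loss
  plateau (patience 5, tolerance 1e-4). The KD pair trains a fixed 30
  epochs each (teacher and student).
- **Probability clipping** at 1e-12 inside every logarithm.
- **Global seed 2022** by default; the pipeline derives the oversampling
  seed (+1) and KD seed (+2) from it. Training is bit-reproducible on one
  machine: every random draw (init, shuffling, dropout) comes from one
  seeded generator per model.
- **Anchor quantile is global** by default. The per-type reading of the
  anchor-selection rule is implemented behind `per_type_quantile=True`; the
  global quantile is consistent with "a 0.3 cutoff selects 30% of the
  target".
- **Metric conventions.** Undefined precision/recall → 0. Macro-F1 and the
  medians average over classes present in the truth; classes that are only
  predicted contribute zero-F1 rows to the per-class table but do not
  change the averaging denominator. Even class counts use midpoint medians.

## The synthetic generator

The generator emulates smoothed gene-activity scores, not fragment counts:
non-negative, non-integer, sparse, cell-type-structured. Per cell of type
`k` and gene `g`:

    score = Bernoulli(1 − p0(m_gk)) · LogNormal(m_gk, 0.5)
    m_gk  = mu_g + marker_effect · 1[g is a marker of k],   mu_g ~ N(0, 0.5)

Detection is mean-dependent: `p0(m) = sigmoid((x0 − m)/0.5)` with the
midpoint `x0` solved (per dataset) so the expected zero fraction equals
`sparsity`. This mirrors accessibility data, where strong marker genes are
rarely missed; under uniform Bernoulli dropout the planted signal is mostly
erased and no classifier — including a construction oracle that knows the
markers — can reach the accuracy regime the method operates in.

Defaults (the study conditions for all simulation tests): 2000 genes, 4
types, 20 markers per type elevated `e² ≈ 7.4`-fold, 70% zeros, 1500 cells
per side, reference type proportions (0.4, 0.3, 0.2, 0.1) with the target's
rotated by one position (composition shift), batch shift 0.8.

The reference→target shift draws one `shift_g ~ N(0, shift_strength)` per
gene, shared across target cells, and adds it to the log-mean *before* both
the magnitude and the detection draws — a multiplicative batch factor acting
at the accessibility level. Acting on realized scores only would be an
additive log-space offset that per-dataset gene standardization removes
almost exactly, leaving round-1 accuracy flat in `shift_strength`; routing
it through detection as well makes the shift genuinely harmful, which is the
regime the two-round design targets. An integer negative-binomial mode
(dispersion 2) exists for robustness testing.

**What passing tests do not show.** The generator's shift is gene-wise and
label-independent; real batch effects can be nonlinear, class-correlated and
accompanied by novel cell types, none of which are modeled. Simulation
results therefore validate the machinery (entropy ranking, anchor mechanics,
distillation) under a controlled shift, not performance on any real tissue.

## Problem sizes

Simulation studies in the test suite and the reproduction script run at the
generator defaults above (1500 + 1500 cells, 2000 genes), with 10 paired
replicates for the anchor-assumption and two-round-gain checks, 3 for the
no-shift control, and 2 replicates × 5 quantile cutoffs for the robustness
check; unit tests use a few hundred cells. These sizes were chosen so the
full suite completes on a single CPU while keeping replicate-level variance
small relative to the effects tested.

## Known limitations

- No rejection option: every target cell receives one of the reference's
  `K` labels, including genuinely novel types.
- The anchor/distillation cycle runs once; it is not iterated.
- Gene identifiers are matched as exact strings; cross-namespace or
  cross-species mapping is the caller's responsibility.
- With very small anchor sets (just above the 1000-cell gate with many
  classes) the oversampled anchor set can still under-represent rare types;
  anchors missing a type leave that type to round-1 calls only.
- Training is CPU-bound numpy; tens of thousands of cells are fine,
  millions are not the design point.
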