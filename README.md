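# twocell

Supervised cell-type annotation for scATAC-seq **gene-score** matrices, using
a two-round strategy: a reference-trained MLP classifier, entropy-based
selection of confidently predicted target cells ("anchors"), and a second
round of teacher–student knowledge distillation trained on those anchors.

## Who this is for

Chromatin-accessibility studies routinely need per-cell type labels, but
supervised transfer from a labeled reference is degraded by the
distributional shift between reference and target experiments (platform,
batch, tissue handling). `twocell` addresses this for gene-score inputs —
per-gene accessibility summaries (e.g. ArchR-style gene activity scores)
used as an expression proxy — by letting the classifier *adapt* to the
target: the second round is trained on cells from the target itself.

## The method

Given a reference gene-score matrix `X_ref ∈ R^{G×N}` with labels `C_ref`
over `K` cell types and a target matrix `X_tgt ∈ R^{G×M}`:

1. **Features & normalization.** Top 3000 genes by one-way ANOVA F-statistic
   across the labeled groups; per cell, scores rescaled to sum to 10,000 and
   log(x+1)-transformed; per gene, standardized to zero mean / unit variance
   (reference and target each with their own statistics).
2. **Round 1.** An MLP (input dropout 0.1; hidden 64 and 16, ReLU; softmax
   head) is trained with cross-entropy `H(p, σ(Z)) = −Σ_i Σ_k p_ik log σ(Z_i)_k`
   on the reference and applied to the target. If `M ≤ 1000` the argmax
   labels are returned.
3. **Anchors.** Per-cell prediction entropy `E_i = −Σ_k q_ik log q_ik` ranks
   target cells by confidence; the lowest-entropy 40% become anchors with
   argmax pseudo-labels, minority types oversampled to the mean per-type
   count.
4. **Round 2 (self-distillation).** A teacher MLP is trained on the anchors;
   a student of the same architecture minimizes
   `L_KD = α·H(p, q_s^{T1}) + (1−α)·KL(q_t^{T2} ‖ q_s^{T2})`
   with `α = 0.1`, `T1 = 1`, `T2 = 3` for 30 epochs, where `q_t^{T2}` are
   the teacher's temperature-softened probabilities. Soft targets make the
   student tolerant of mislabeled anchors. Non-anchors take the student's
   calls; anchors keep their round-1 labels.

Evaluation helpers report accuracy, adjusted Rand index, macro-F1, Cohen's
κ, and median per-class F1/precision/recall.

## Worked example

```python
import twocell as tc

# a synthetic benchmark pair with a known gene-wise batch shift
ds = tc.generate(tc.SyntheticConfig(seed=7, shift_strength=0.8))

result = tc.run_two_round(ds.ref, ds.ref_labels, ds.target,
                          n_features=2000, random_state=2022)
truth = ds.target_labels.labels
print("rounds run:", result.n_rounds)
print("anchors:", int(result.is_anchor.sum()), "of", len(truth))
print("round-1 accuracy:", round((result.first_round_labels == truth).mean(), 3))
print("final accuracy:  ", round((result.final_labels == truth).mean(), 3))
```

Output:

```
rounds run: 2
anchors: 600 of 1500
round-1 accuracy: 0.993
final accuracy:   0.999
```

1500 target cells exceed the 1000-cell gate, so the second round runs; 40%
of cells (600) are anchors. On this replicate the distillation round
corrects most of the remaining shift-induced error among non-anchors; over
replicate seeds the final accuracy is on average at or above round 1
(see the reproduction script below).

The same pipeline is available from the shell:

```bash
twocell simulate --out data/ --seed 2022
twocell train   --ref data/reference --labels data/reference_labels.csv --model model.npz
twocell predict --model model.npz --target data/target --out predictions.csv
twocell eval    --pred predictions.csv --truth data/target_labels.csv
```

## Layout

- `twocell.io` — Matrix Market / dense-table / label-table readers, writers
- `twocell.preprocess` — F-test selection, normalization, standardization
- `twocell.models` — `TemperedMLP`, `KDClassifier`, losses, persistence
- `twocell.tworound` — entropy, anchors, `TwoRoundAnnotator`, `run_two_round`
- `twocell.metrics` — `evaluate` (seven-metric report)
- `twocell.synthetic` — labeled reference/target generator with batch shift
- `twocell.cli` — `twocell train|predict|simulate|eval`

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
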