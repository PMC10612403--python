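# attnzyme

Enzymes are classified by four-level Enzyme Commission (EC) numbers
(`class.subclass.sub-subclass.serial`, top-level class 1–7 with 7 =
translocases). Predicting an EC number from a protein's amino-acid sequence
alone is a standard testbed for sequence-based functional annotation, and
transformer encoders fine-tuned with a CLS classification head are the
state of the art for it. A further question matters as much as raw
accuracy: *which residues does the model rely on?* For enzymes there is an
unusually solid answer key — curated catalytic residues — so
interpretability methods can be benchmarked quantitatively rather than by
eye.

`attnzyme` is a desk-scale toolkit for that whole methodology:

- **`TransformerECClassifier`** — a scikit-learn-style estimator wrapping a
  compact numpy self-attention encoder (fixed sinusoidal positions, CLS
  readout with layer-norm + dropout + linear head, flat cross-entropy over
  classes). The training loop implements the reference fine-tuning recipe:
  Adam(β₁=0.9, β₂=0.999), learning rate `lr(e) = lr0 · 0.8^e`, gradient
  accumulation (default effective batch 2 × 16), dropout 0.2 on the CLS
  embedding only, and optional inverse-frequency balanced sampling. Every
  attention map of a forward pass is capturable as a row-stochastic tensor
  of shape `(L·H, T, T)`, and gradients w.r.t. the input embeddings are
  exposed for saliency methods.
- **Attention aggregation (`AttnAgg` family)** — two-stage pooling of the
  attention tensor (average or maximum over the head or query axis, then
  over an axis of the remaining matrix) into one importance score per
  residue. The 16 nominal variants collapse to 13 functionally distinct
  ones; `AttnAgg1A1A`, the mean attention each residue *receives*, is the
  headline method.
- **Saliency baselines** — gradient norm, gradient×input, integrated
  gradients (midpoint rule, positional-encoding baseline, completeness
  checked), attention-last-layer, attention rollout, a LIME-style masked
  perturbation surrogate, and a shuffled-score null.
- **Interpretability evaluation** — top-k F1 curves, pooled
  precision–recall-gain curves (`gain(x) = (x − π)/((1 − π)x)` at
  prevalence π, so 0 is the always-positive classifier and 1 is perfect),
  maximum F-Gain over a global threshold sweep with per-sequence rescaling,
  and one-sided exact binomial enrichment tests for top-n hit counts.
- **Hierarchical EC evaluation** — macro precision/recall/F1 and accuracy
  at levels 0 (enzyme vs non-enzyme) through 4, all derived by truncating a
  single level-4 prediction, under both the enzymes-only and
  all-sequences protocols.
- **Benchmark construction** — time-based splits with a 40%-identity
  leakage guard: cluster training + new-release sequences (external
  cluster tables or the built-in greedy aligner-based clusterer), discard
  every cluster touching the training release, and test on one
  representative per surviving cluster.
- **Synthetic fixtures** — seeded generators for motif-classed sequences
  with planted "catalytic" residues at ~1.2% prevalence, planted-hotspot
  attention tensors, and paired sequence releases with known cluster
  structure, so the full pipeline runs and is tested without downloads.

## Worked example

Train a small encoder from scratch on synthetic motif-classed sequences,
then check that the attention the model pays lines up with the planted
catalytic residues:

```python
from attnzyme import (SyntheticSpec, gen_classified_sequences,
                      TransformerECClassifier, attn_agg, compare_methods)

spec = SyntheticSpec(n_sequences=150, length_range=(80, 120), seed=0)
records, labels, gold, motifs = gen_classified_sequences(spec)
X = [r.sequence for r in records]
y = [labels[r.id] for r in records]

clf = TransformerECClassifier(learning_rate=1e-3, accumulation_steps=1,
                              n_epochs=5, balance_sampling=True, random_state=0)
clf.fit(X[:120], y[:120], validation_data=(X[120:], y[120:]))
print([round(h["valid_accuracy"], 2) for h in clf.history_])

importances, gold_eval = [], {}
for rec in records[120:]:
    _, capture = clf.forward_with_attention(rec.sequence)
    capture.seq_id = rec.id
    iv = attn_agg(capture, "AttnAgg1A1A")
    importances.append(iv)
    gold_eval[rec.id] = gold[rec.id]

report = compare_methods({"Attn agg": importances}, gold_eval,
                         rescale_mode="minmax", shuffle_reps=10, seed=1)
print(report.as_text())
```

Output:

```
[0.33, 0.67, 1.0, 1.0, 1.0]
Method                  PRG-AUC (x100)  Max F-Gain (%)  Time (s)
Random                     11.56±9.29     52.88±2.04
Attn agg                        100.00           99.96      0.00
```

The classifier reaches perfect held-out accuracy by epoch 3, and
`AttnAgg1A1A` ranks every planted catalytic residue above every background
residue (PRG-AUC 100, max F-Gain ~100), while the same scores shuffled
within each sequence sit near chance. The same workflows are available
from the shell via the `attnzyme` command (`simulate`, `build-split`,
`train`, `predict`, `interpret`, `eval-interp`, `eval-ec`), each writing a
reproducible run manifest.

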