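# Methods

## The model

The classifier is a standard transformer *encoder* operating on amino-acid
tokens. Each residue maps to a learned embedding, scaled by √d and summed
with a fixed sinusoidal positional encoding; a single CLS token is placed
at position 0 so that its positional encoding is identical for every
sequence. Ambiguous residue letters (B, J, O, U, Z, …) map to the wildcard
token `X`; non-letter characters are rejected, as are sequences longer
than `max_len − 1` (no silent truncation). Each of the `L` layers applies
multi-head self-attention (H heads, row-softmax over the attended axis)
and a GELU feed-forward block, both post-norm with residual connections.
The CLS embedding of the final layer passes through a layer norm, dropout
(training only), and a linear projection to class logits; classes are flat
and independent, trained with cross-entropy.

The encoder is implemented directly in numpy with hand-written
backpropagation. That choice is what makes the rest of the package simple:
every attention map is captured as a `(L·H, T, T)` row-stochastic tensor
without framework hooks, and the gradient of any logit with respect to the
input embeddings — the primitive all gradient-based saliency methods need —
is one function call. Gradient correctness is pinned by finite-difference
tests.

### Training recipe and defaults

| parameter | default | meaning |
|---|---|---|
| dropout_cls | 0.2 | dropout on the CLS embedding only |
| batch_size × accumulation_steps | 2 × 16 | effective batch 32 |
| learning_rate (lr0) | 1e-5 | Adam step size at epoch 0 |
| beta1, beta2 | 0.9, 0.999 | Adam moments |
| lr_decay | 0.8 | lr(e) = lr0 · 0.8^e, exactly |
| n_epochs | 15 | fine-tuning epochs |
| balance_sampling | off | sampling with replacement, weight 1/class count |
| random_state | 0 | one seed for init, sampling and dropout |

These defaults are the reference fine-tuning recipe and make sense for
adapting a large pretrained encoder. The synthetic end-to-end experiments
in the test suite train *from random initialisation*, which needs a larger
step and more optimizer steps: they use `learning_rate=1e-3` and
`accumulation_steps=1` (300 examples at effective batch 32 would give only
8 updates per epoch), everything else at defaults. Gradient accumulation
is implemented as an effective batch — the mean gradient over
`batch_size × accumulation_steps` examples per Adam step — which makes the
(batch 2, accum 2) ≡ (batch 4, accum 1) equivalence exact.

## Attention aggregation

All attention maps of one forward pass form a tensor `A[h, i, j]`: head
slot h (layer-major), attending token i, attended token j, with each row
over j summing to 1. Stage 1 collapses the head axis (code `1`) or the
query axis (code `2`) with the average (`A`) or maximum (`M`); stage 2
collapses one axis of the remaining matrix the same way. `AttnAgg1A1A`
therefore scores token j by `mean_h mean_i A[h, i, j]` — the average
attention j *receives* — and is algebraically identical to `AttnAgg2A1A`
because nested averages over fixed axes commute (the same argument applies
to the double maximum). Aggregation runs on the full token matrix
including CLS; the CLS score is removed afterwards.

Deduplicating the 16 nominal variants is done numerically: every variant
is evaluated on seeded random tensors with Dirichlet(1) rows (the
least-informative distribution on the simplex), probe shapes keep the head
count different from the token count so axis mix-ups cannot alias, and
variants merge when their outputs agree within 1e-9 on every probe.
Variants whose output is *constant* on every probe — averaging the key
axis of row-stochastic rows always yields 1/T — carry no ranking
information and merge into a single degenerate class. Under this
convention 16 variants yield 13 classes: two average-commutation merges,
two maximum-commutation merges counted as one pair each, and the two
constant variants as one class. Variants whose surviving axis is the head
axis are computed but flagged degenerate (they score heads, not residues).

## Saliency baselines

All baselines emit the same per-residue `ImportanceVector` contract
(special tokens stripped, scores indexed by 1-based position):

- **Grad / Grad×input** — Euclidean norm over embedding dimensions of the
  target-logit gradient (optionally multiplied elementwise by the input
  embedding). The target class defaults to the predicted class; gradient
  methods are nearly class-agnostic in practice, and the choice is
  configurable.
- **Integrated gradients** — midpoint Riemann sum of gradients along the
  straight path from a baseline to the input, attributions
  `(x − b) ⊙ mean_k ∇f`. The baseline keeps the fixed positional encoding
  and zeroes only the token embeddings. This is deliberate: layer-normed
  encoders are nearly scale-invariant, so a fully zero baseline
  concentrates the entire path integral in an α-neighbourhood of the
  origin narrower than 1e-5 and the completeness axiom becomes numerically
  unattainable at any practical step count (measured directly during
  development). With the positional baseline, completeness holds within 1%
  at 200 steps and is asserted in the tests.
- **Attention last layer** — head-averaged final-layer map; the default
  readout is the column mean (attention received), which makes the method
  coincide with `AttnAgg1A1A` on a single-layer sub-tensor; a CLS-row
  readout is available.
- **Rollout** — per layer, the head-averaged map is mixed with identity
  (0.5/0.5, configurable) and row-normalised; the mixtures are multiplied
  from first to last layer and the CLS row of the product is the readout.
- **LIME-style surrogate** — 5000 perturbations by default (the cost that
  makes LIME orders of magnitude slower than one prediction): each residue
  is independently masked to `X` with rate 0.3; a weighted least-squares
  fit of the target-class probability on the binary presence matrix, with
  weights `exp(−Hamming/width)` and width 0.25·length, gives signed
  coefficients. Constant design columns get coefficient 0 with a warning.
- **Shuffled baseline** — scores permuted within each sequence, repeated
  (default 10×), metrics reported as mean ± sd.

## Interpretability metrics

Catalytic residues are ~1% of all residues, so the metrics live in
precision–recall space. Scores are first rescaled per sequence (min-max,
z-score — the reading chosen for the ambiguous "normalization" — L1, L2,
or none; the same pipeline feeds both the PR curve and the threshold
sweep), then pooled across all residues of all sequences.

**PRG curves.** Precision and recall at every threshold are transformed to
gains, `gain(x) = (x − π)/((1 − π)x)`; the always-positive classifier has
precision π, hence precision-gain 0, and perfection maps to 1. The curve
keeps points with recall-gain ≥ 0 (interpolating the segment that crosses
zero, or extending the leftmost point flat to 0 when every observed point
is already positive), clips precision-gain to [0, 1], and integrates by
trapezoid over recall-gain ∈ [0, 1]. An exhaustive threshold-enumeration
oracle written with explicit loops pins the implementation in the tests.

**Max F-Gain.** Thresholds sweep every unique pooled score plus +∞ with
the strict rule "score > threshold"; each F1 is mapped to gain space by
the same formula and the maximum is reported ×100. Two conventions matter
and are deliberate: the sweep never includes the all-positive cut (strict
inequality at the minimum score never selects everything), and
non-positive gains clip to 0 — so constant scores score exactly 0, and a
perfectly separating method scores 100. Note that under the raw gain
formula an explicit always-positive classifier would score 0.5, not 0; the
clipped sweep is what makes "no usable threshold" and "reference
classifier" coincide at 0.

**Enrichment.** The top-n enrichment test is a one-sided exact binomial
tail: P(X ≥ hits) with n = top_n and success rate annotated/length. The
printed worked examples (6/10 vs 21/271 → 0.00003; 2/10 vs 10/907 →
0.00516) are reproduced to the reported 5-decimal rounding; the exact tail
is also checked against full outcome enumeration. (These values are
binomial tails, not Pearson chi-squared statistics, even though such
enrichments are often loosely reported under that name.)

## Hierarchical EC evaluation

Level-4 predictions (or the non-enzyme label) are truncated to each level
0–4; level 0 collapses every EC to "enzyme". Macro precision/recall/F1
average over the classes *present in the truth* at that level (zero-truth
classes are excluded; per-class F1 with zero precision and recall is 0),
accuracy is exact-match at that level. Both standard protocols are
first-class: enzymes-only (level 0 on everything, levels 1–4 on true
enzymes) and all-sequences (non-enzyme is a class at every level).
Class counts are always derived from the data at hand and reported in
`LevelMetrics.n_classes`.

## Benchmark construction

The split guards against homology leakage: training-release and
new-release sequences are clustered at 40% identity; any cluster touching
the training release is discarded; the longest member (ties by id) of each
surviving cluster becomes a test sequence; all training-release members
stay in training (keep-all), and an optional validation fraction is drawn
from training clusters only, so the no-shared-cluster guarantee is
unaffected. The canonical path consumes an external two-column cluster
table; the built-in greedy clusterer (global alignment, match 1, mismatch
0, gap −1; identity = identical positions / alignment length; visiting
order by decreasing length) exists so the guarantee is testable without
external binaries. Length presets: strict 41–1024 and inclusive 40–1000.
Records carrying a catalytic-activity GO flag but no EC number are neither
enzymes with a class nor non-enzymes; they are excluded from both.

## Synthetic fixtures

`gen_classified_sequences` plants one class-specific 5-mer motif per
sequence; motif positions are the gold "catalytic" labels. Defaults — 300
sequences of 380–460 residues — put gold prevalence at ≈1.2%, the sparse
regime curated catalytic annotations occupy. Each class owns a reserved
two-letter alphabet from which its motif is drawn, and the background is
uniform over the remaining 14 amino acids, so motif letters occur only at
planted positions. This mirrors the sense in which catalytic residues are
chemically distinctive, and it is also what makes the task learnable at
desk scale: with motifs drawn from the full background alphabet, a small
from-scratch encoder must learn exact positional k-mer matching from a
few hundred examples and plateaus near 0.75 accuracy (it memorizes
instead of generalizing) — measured during design, before the recovery
thresholds were frozen. What the passing end-to-end tests therefore show
is that the pipeline (training → attention capture → aggregation →
gain-space evaluation) recovers a genuine planted signal and that the
shuffled null does not; they do not show that attention finds catalytic
sites in real enzymes, which needs a pretrained encoder and curated data.

`gen_attention_tensor` draws Dirichlet(1) rows and adds `boost/n_hotspots`
to hotspot columns before renormalising: boost 0 is exchangeable noise
(rankings uniform, interpretability metrics at chance), boost 10 puts
every hotspot column above every background column with certainty, giving
per-tensor PRG-AUC 1. `gen_release_pair` emits an old release plus mutated
copies (i.i.d. substitutions, expected identity ≈ 1 − rate, no indels so
identity is analytically predictable) and fresh sequences, with ground
truth for split assertions.

All generators are pure functions of their spec including the seed.

## Numerical choices and degenerate inputs

- Layer-norm ε = 1e-5; Adam ε = 1e-8; attention-row validation tolerance
  1e-5; variant dedup tolerance 1e-9; oracle agreement 1e-12.
- Ranking ties break by ascending residue position (stable sort) wherever
  top-k sets are formed.
- Rescaling of constant score vectors yields zeros (min-max, z-score) or
  zeros for zero norms (L1/L2).
- Prevalence 0 or 1 makes gains undefined and raises; an empty test set
  after cluster exclusion warns rather than raises.
- Training with 0 epochs returns the seeded initial state and an empty
  log; a class present only in validation warns.

## Known limitations

- The encoder is desk-scale (default 2 layers, 4 heads, d=64); nothing in
  the code changes at larger configurations, but no pretrained weights are
  provided or loaded, so absolute accuracies on real benchmarks are out of
  reach here.
- The greedy clusterer is quadratic in the number of representatives and
  intended for fixtures and small studies, not proteome-scale clustering.
- LIME cost is linear in `lime_samples` forward passes per protein;
  the default 5000 is faithful but slow on long sequences.
- Multi-label (multifunctional) enzymes are out of scope; one EC per
  sequence.
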