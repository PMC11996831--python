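# Methods

## Overview

`protfuse` classifies protein sequences as disease-associated or background
in three stages: (1) corpus curation — residue cleaning, CD-HIT-style
redundancy removal, and balanced negative sampling; (2) embedding — each
sequence becomes one fixed-length numeric vector, either from an external
protein language model (PLM) or from the package's deterministic synthetic
embedder; (3) classification — a hybrid neural network with parallel
Transformer-encoder and CNN branches whose features are combined by a
learned attention gate. Evaluation is stratified five-fold cross-validation
with confusion-matrix metrics, ROC/AUC and PR/AUPR.

## Corpus curation

**Cleaning.** Sequences are upper-cased and restricted to the 20 canonical
residues. Non-canonical codes (B, Z, J, U, O, X, `*`, gaps) are handled by
policy: `substitute-X` (default) replaces each with `X`, preserving length
so downstream positional operations (prefix truncation, segment shuffling)
keep their coordinates; `strip` deletes them; `drop` rejects the record.

**Redundancy filtering.** The filter mirrors the greedy longest-first
strategy of CD-HIT: records are processed by decreasing length (ties broken
by id for determinism); each record joins the first cluster whose
representative shares at least the identity threshold (default 0.9), else
founds a cluster; representatives are kept. Identity is estimated as the
fraction of the shorter sequence's distinct 5-mers found in the longer
sequence. This estimate is exact for identical sequences and a lower bound
in general: a contiguous divergent block covering fraction *f* of length
*L* gives k-mer identity ≈ 1 − f − (k−1)/L versus alignment identity
1 − f. The two measures therefore agree on the 0.9 decision when
differences are localized and L ≳ 100 aa; dispersed point mutations at
3–10% push the k-mer estimate far below the alignment value, which is why
the test suite verifies decisions against an exact global-alignment oracle
(edlib) rather than assuming the approximation. An optional adapter can
invoke an external `cd-hit` binary when one is installed; the built-in
filter is the default so nothing needs downloading.

**Negative sampling.** Negatives are drawn uniformly without replacement
from a background pool, excluding any record matching a positive by id or
exact sequence, in numbers equal to the filtered positives (balanced
classes). The draw is order-independent and reproducible from its seed. By
default sampled negatives are also redundancy-filtered and topped back up
to balance.

## Embedding

`embed_with_plm` adapts an ESM-family model: final-layer per-residue
representations are pooled to one vector per sequence (mean over residues
by default; the BOS/CLS token is available). Sequences beyond the model
context (1022 aa) are truncated with a warning. When no PLM runtime is
importable the adapter raises an error pointing at the synthetic embedder.

`embed_synthetic` is a first-class, fully deterministic stand-in with three
components per vector:

1. **Composition signal** — 3-mer counts hashed (CRC32) into `num_feature`
   bins and normalized by √(#k-mers), so the signal has O(1) scale at any
   length. This ties the embedding to sequence content: planted motifs
   raise specific bins, and shuffling or truncating a sequence changes its
   vector.
2. **Class shift** — positives receive a mean shift of magnitude
   `class_shift` on a fixed coordinate subset, half of it a contiguous
   block (spatially localized after the CNN's grid reshape) and half
   strided across the vector (dispersed), so both branches can see class
   signal.
3. **Noise** — Gaussian with scale `noise_sd`, seeded per record from
   `(seed, sequence)`; a vector never depends on batch composition, and
   identical sequences map to identical vectors.

Separability is governed by `class_shift / noise_sd`; at ratio 5 and
n = 200/class a logistic regression reaches ≥ 0.99 held-out accuracy.
What the synthetic embedder does **not** emulate: the geometry of real PLM
representations (anisotropy, evolutionary structure, long-range contacts).
Pipeline results on synthetic data demonstrate that the machinery recovers
planted signal and respects its contracts — not that any particular
accuracy transfers to real disease-gene corpora.

Embeddings are standardized per coordinate (zero mean, unit variance)
using training-fold statistics only, so no information leaks from held-out
folds.

## Classifier

Input is a batch X of n samples × `num_feature`. `d_model` equals
`num_feature`.

**Transformer branch.** The reference architecture treats the sample axis
as the token axis: self-attention runs *across the samples of a batch*
("batch-as-tokens"). We implement this faithfully as the default
(`token_mode="batch"`), which makes every prediction depend on its
evaluation batch; evaluation therefore always uses one fixed, documented
batch — the whole held-out fold. A leakage-free `chunk` mode that splits
one embedding into tokens of width `d_model` is available behind a flag.
Each encoder layer is a standard pre-norm block: layer norm → multi-head
scaled-dot-product attention (d_k = d_model / n_head; per-head
A = softmax(QKᵀ/√d_k) row-stochastic) → residual, then layer norm →
position-wise feed-forward (width 4·d_model, ReLU) → residual, dropout 0.1
after each sublayer. No positional encoding is added — samples are a set,
and the branch is exactly permutation-equivariant. Default depth is 2
encoder layers (1–6 supported for the depth sweep).

**CNN branch.** Each vector is zero-padded to the next perfect square
(e.g. 1280 → 36² with 16 pads — PLM widths are rarely squares), reshaped
row-major to a single-channel side×side grid, convolved (valid extent,
default 8 output channels, 3×3 kernel), passed through ReLU, max-pooled
(non-overlapping 2×2, stride = window, trailing remainder cropped, ties to
the first element for determinism), and flattened.

**Fusion.** With branch features T and C, a two-layer scorer produces a
per-sample gate a = softmax(W₂ tanh(W₁[T;C] + b₁) + b₂) ∈ ℝ², a_t + a_c = 1.
The gate is computed row-wise — per sample — because a single global gate
would be a batch-dependent constant rather than a feature modulator. By
convention the first gate component weights the Transformer branch (the
source description is inconsistent on this ordering; we fix and document
it). Fused features are F = [a_t·W_t T ; a_c·W_c C], classified by one
fully connected layer into two logits with softmax; the decision threshold
is 0.5. Ablation variants: `no-fusion` (plain concatenation [T;C]),
`cnn-only`, `transformer-only`.

**Training.** Softmax cross-entropy minimized by mini-batch Adam
(lr 1e-3, batch 64, ≤ 100 epochs, dropout 0.1), early stopping with
patience 10 on validation loss when a validation split is supplied
(cross-validation monitors the held-out fold, matching the protocol in
which that fold is the "validation set") or on training loss otherwise.
The best-loss parameters are returned together with the per-epoch loss
trace. All forward/backward passes are hand-written NumPy; gradients were
verified against central finite differences (relative error < 1e-6 for
every parameter tensor in every variant). Everything is reproducible from
the config seed. Non-finite losses or activations abort training with the
last finite-loss checkpoint attached; layer norm, Adam's per-coordinate
scaling and clipped cross-entropy make this architecture hard to diverge
in practice.

## Evaluation

Confusion-matrix metrics (accuracy, precision, recall/TPR, F1, MCC, FPR)
are computed directly from TP/FP/TN/FN; any metric with a zero denominator
is reported as 0 and flagged rather than raising, because degenerate folds
occur in ablation runs. ROC curves come from a descending threshold sweep
with tied scores grouped; AUC is the trapezoidal area (equal to the
normalized Mann–Whitney U statistic) and AUPR is step-interpolated average
precision (linear PR interpolation is biased optimistic). Folds are
stratified (the corpus is balanced; stratification makes per-fold balance
deterministic), and the reported aggregate is the arithmetic mean of
per-fold metrics. Per-fold ROC/PR points are emitted for plotting.

## Experiment harnesses

All harnesses compute one fold split per dataset and reuse it across
conditions, so every comparison is paired.

* **Ablation grid** — any subset of {full, no-fusion, cnn-only,
  transformer-only} × encoder depth 1–6.
* **Incomplete sequences** — prefix truncation at 500 aa (idempotent;
  shorter sequences unchanged).
* **Shuffle noise** — per sequence, one contiguous window of length
  round(ratio·L) at a seeded uniform position has its residues uniformly
  permuted; length and residue multiset are conserved and everything
  outside the window is untouched. A multi-window mode (m disjoint windows
  summing to the ratio) exists behind a flag; the single-window reading is
  the default. The sweep re-embeds each perturbed corpus (perturbation
  acts on sequences, not vectors), caching embeddings by corpus content
  digest so ratio 0 reproduces the unperturbed result bit-for-bit.

## Synthetic study conditions

The generator emits two classes over the 20-letter alphabet with matched
length distributions. Positives carry a planted 8-residue motif (2 copies,
non-overlapping) in an exact ⌈motif_rate·n⌉ subset of base records — exact
rather than Bernoulli so the motif-recovery floor holds by construction.
With `positional_signal` the motifs land inside the first 500 residues, so
truncation at 500 retains class signal while heavy shuffling destroys it.
Near-duplicates copy a base record and rewrite one contiguous block
(default 5% of length); each base has at most one duplicate, so every
near-identical pair in the corpus is a manifest-recorded planted pair
(independent duplicates of one base would be ~10% apart from each other,
straddling the 0.9 threshold ambiguously). The manifest records motif
positions, duplicate pairings, and the generating spec.

Default problem sizes used by the test suite and the acceptance script,
chosen as the smallest scales at which the statistical contrasts are
clear-cut: 500/class (lengths 100–400, embedding dim 64) for
cross-validated signal recovery and its null control; 200/class for the
ablation grid; 150/class (lengths 100–600, `noise_sd` 0.05, class signal
from motifs only) for the positional-signal robustness sweep; 100/class
with 20% near-duplicates for the filtering study. The synthetic embedder's
default dimension is 1280 to match common PLM widths; the studies above
use 64 so the grid is 8×8 and training stays light.

## Numerical choices and edge cases

* Softmax is computed with max-subtraction; attention rows and fusion
  gates sum to 1 within 1e-6.
* Xavier-uniform initialization, seeded; fold f trains with seed
  `base_seed + 1000·(f+1)`.
* Standardization guards constant coordinates (unit divisor).
* Max-pool ties resolve to the first window element; pooling crops any
  trailing remainder (side not divisible by window).
* `reshape_to_grid` of a width-d vector pads with zeros to ⌈√d⌉².
* Cross-entropy clips probabilities at 1e-12 before the log.
* Single-token attention degenerates to weight 1 on the sole token.

## Known limitations

* Batch-as-tokens attention couples predictions to the evaluation batch;
  scores are only comparable across runs that fix the batch, which the
  evaluation protocol does. Use `token_mode="chunk"` for deployment-style
  per-sample inference.
* The k-mer identity estimate undercounts dispersed divergence; the filter
  is calibrated for near-duplicate removal, not remote-homology clustering.
* Pure-NumPy training is single-threaded BLAS-bound and intended for
  desk-scale corpora (thousands of sequences), not GPU-scale work.
* Synthetic corpora make no claim of biophysical realism; see the
  embedding section for what passing tests do and do not establish.
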