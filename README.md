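# protfuse

Hybrid Transformer–CNN classification of protein sequences for
disease-gene prioritization.

Given protein sequences labeled disease-associated (positive) or
background (negative), `protfuse` curates the corpus, embeds every
sequence into a fixed-length vector with a protein language model (or a
deterministic synthetic embedder), and classifies the vectors with a
neural network that runs a Transformer encoder and a CNN in parallel and
combines their features through a learned attention gate. It is aimed at
computational biologists who want a self-contained, reproducible pipeline
for sequence-based gene prioritization — including its evaluation
protocol, ablation grid, and sequence-perturbation robustness studies —
without GPU infrastructure or external downloads.

## The model

Each sequence becomes an embedding x ∈ ℝ^d (d = `num_feature` = `d_model`).
A batch X of n samples is processed by two branches:

* **Transformer branch** — multi-head scaled-dot-product self-attention
  with per-head width d_k = d_model / n_head:
  Q_i = X′W_i^Q, K_i = X′W_i^K, V_i = X′W_i^V,
  A_i = softmax(Q_iK_iᵀ/√d_k), O_i = A_iV_i, with head outputs
  concatenated and projected by W^O, inside standard pre-norm encoder
  blocks (feed-forward width 4·d_model, residuals, layer norm). Following
  the reference architecture, attention runs across the samples of the
  batch; evaluation therefore uses one fixed batch (the whole fold).
* **CNN branch** — x is zero-padded to the next perfect square, reshaped
  to a ⌈√d⌉×⌈√d⌉ single-channel grid, convolved (valid extent, ReLU),
  max-pooled (non-overlapping), and flattened.

With branch features T and C, a per-sample gate
a = softmax(W₂ tanh(W₁[T;C] + b₁) + b₂), a_t + a_c = 1, reweights the
branches: F = [a_t·W_t T ; a_c·W_c C], and a fully connected layer with
softmax yields the positive-class probability (threshold 0.5). Training
is mini-batch Adam on cross-entropy, implemented entirely in NumPy with
hand-written backpropagation (finite-difference verified). Evaluation is
stratified five-fold cross-validation reporting accuracy, precision,
recall, F1, MCC, FPR, AUC and AUPR with per-fold ROC/PR curves.

Corpus curation mirrors standard practice: residue canonicalization,
greedy longest-first redundancy filtering at 90% identity (CD-HIT style,
k-mer identity estimate), and balanced negative sampling that excludes
any overlap with the positives.

## Worked example

```python
import numpy as np
from protfuse import (GeneratorSpec, generate_corpus, redundancy_filter,
                      embed_synthetic, cross_validate, ModelConfig)

spec = GeneratorSpec(n_per_class=150, length_range=(100, 400), seed=0)
records, manifest = generate_corpus(spec)
print(f"{len(records)} records, {len(manifest['duplicates'])} planted near-duplicates")

kept, summary = redundancy_filter(records, identity_threshold=0.9)
print(f"kept {len(kept)} after redundancy filtering (removed {summary.n_removed_redundant})")

labels = np.array([1 if r.label == "positive" else 0 for r in kept])
emb = embed_synthetic(kept, num_feature=64, class_shift=1.0, noise_sd=1.0, seed=1)
report = cross_validate(emb, labels, ModelConfig(d_model=64, seed=2, max_epochs=60),
                        k=5, seed=3)
for name in ("accuracy", "precision", "recall", "f1", "mcc", "auc", "aupr"):
    print(f"{name:>9}: {report.aggregate[name]:.4f}")
```

Output:

```
300 records, 30 planted near-duplicates
kept 270 after redundancy filtering (removed 30)
 accuracy: 0.8000
precision: 0.8006
   recall: 0.7926
       f1: 0.7956
      mcc: 0.6014
      auc: 0.8609
     aupr: 0.8725
```

The generator planted 30 near-duplicate copies and the 0.9-identity
filter removed exactly those 30. At a moderate embedding separation
(class shift equal to the noise scale) the cross-validated hybrid model
ranks positives above negatives with mean AUC ≈ 0.86; raising
`class_shift` to 5 drives every metric to ≈ 1.0, and setting it to 0 with
`motif_rate=0` leaves AUC at chance — the two controls that bracket the
pipeline.

The same pipeline is scriptable from the shell:

```
protfuse simulate --seed 1 --out corpus/
protfuse embed --fasta corpus/corpus.fasta --labels corpus/labels.tsv \
         --dim 64 --class-shift 1.0 --seed 2 --out emb.h5
protfuse evaluate --emb emb.h5 --labels corpus/labels.tsv --folds 5 --out report/
```

`protfuse ablate` runs the architecture ablation grid (fusion on/off,
single branches, encoder depth 1–6) under one shared fold split;
`protfuse perturb` runs the contiguous-segment shuffle robustness sweep;
`protfuse truncate` keeps only the first N residues; `protfuse prepare`
curates a real FASTA corpus against a background pool. Real
protein-language-model embeddings are supported through
`embed_with_plm(records, model_name)` when a PLM runtime (`fair-esm` +
`torch`) is installed.

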