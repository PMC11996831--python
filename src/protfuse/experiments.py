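"""Reproducible experiment harnesses.

Three protocols around the classifier: the architecture ablation grid
(fusion on/off, single branches, encoder depth 1-6), prefix truncation to
emulate incomplete sequences, and a contiguous-segment shuffle sweep that
injects sequence-level noise at increasing ratios. All harnesses share a
single fold split so every row of a results table is a paired comparison.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .corpus import ProteinRecord, sequence_digest
from .embedding import EmbeddingSet
from .errors import ParameterError
from .evaluation import FoldReport, cross_validate, kfold_split
from .model import ModelConfig


@dataclass(frozen=True)
class AblationSpec:
    """One row of the ablation grid."""

    variant: str = "full"  # full | no-fusion | cnn-only | transformer-only
    n_encoder_layers: int = 2

    def __post_init__(self):
        if not (1 <= self.n_encoder_layers <= 6):
            raise ParameterError("n_encoder_layers must be in 1..6 for the ablation grid")

    @property
    def name(self) -> str:
        if self.variant == "cnn-only":
            return "cnn-only"
        return f"{self.variant}-enc{self.n_encoder_layers}"


@dataclass(frozen=True)
class NoiseSpec:
    """One sequence-perturbation condition."""

    shuffle_ratio: float = 0.0
    truncate_at: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.shuffle_ratio <= 1.0):
            raise ParameterError("shuffle_ratio must be in [0, 1]")
        if self.truncate_at is not None and self.truncate_at < 1:
            raise ParameterError("truncate_at must be >= 1")


def truncate_sequences(
    records: Sequence[ProteinRecord], limit: int = 500
) -> list[ProteinRecord]:
    """Keep only the first ``limit`` residues of each sequence (idempotent)."""
    if limit < 1:
        raise ParameterError(f"limit must be >= 1, got {limit}")
    return [replace(r, sequence=r.sequence[:limit]) for r in records]


def shuffle_segment(
    record: ProteinRecord,
    ratio: float,
    seed: int,
    n_windows: int = 1,
) -> ProteinRecord:
    """Permute the residues inside seeded contiguous window(s).

    One window of length ``round(ratio * L)`` (default) is placed uniformly
    at random and its residues are uniformly permuted; everything outside
    is untouched, so sequence length and residue multiset are conserved.
    ``n_windows > 1`` splits the shuffled mass over that many disjoint
    windows. The randomness derives from ``(seed, record id)`` so each
    record's perturbation is independent of corpus order.
    """
    if not (0.0 <= ratio <= 1.0):
        raise ParameterError(f"ratio must be in [0, 1], got {ratio}")
    if n_windows < 1:
        raise ParameterError("n_windows must be >= 1")
    L = len(record.sequence)
    total = round(ratio * L)
    if total < 2:
        return record
    rng = np.random.default_rng([seed, zlib.crc32(record.id.encode())])
    lengths = [total // n_windows] * n_windows
    lengths[0] += total - sum(lengths)
    chars = list(record.sequence)
    occupied: list[tuple[int, int]] = []
    for wlen in lengths:
        if wlen < 2 or wlen > L:
            continue
        for _ in range(200):
            start = int(rng.integers(0, L - wlen + 1))
            if all(start + wlen <= s or start >= e for s, e in occupied):
                break
        else:
            continue
        occupied.append((start, start + wlen))
        perm = rng.permutation(wlen)
        window = chars[start : start + wlen]
        chars[start : start + wlen] = [window[p] for p in perm]
    return replace(record, sequence="".join(chars))


def perturb_corpus(
    records: Sequence[ProteinRecord], spec: NoiseSpec, n_windows: int = 1
) -> list[ProteinRecord]:
    """Apply truncation and/or segment shuffling to a whole corpus."""
    out = list(records)
    if spec.truncate_at is not None:
        out = truncate_sequences(out, spec.truncate_at)
    if spec.shuffle_ratio > 0:
        out = [shuffle_segment(r, spec.shuffle_ratio, spec.seed, n_windows) for r in out]
    return out


def run_ablation_grid(
    embeddings: EmbeddingSet,
    labels: Sequence[int],
    specs: Sequence[AblationSpec],
    base_config: ModelConfig,
    k: int = 5,
    seed: int = 0,
) -> dict[str, FoldReport]:
    """Cross-validate one model per ablation spec on a shared fold split."""
    y = np.asarray(labels, dtype=int)
    folds = kfold_split(len(embeddings), k, y, seed)
    results: dict[str, FoldReport] = {}
    for spec in specs:
        cfg = asdict(base_config)
        cfg["variant"] = spec.variant
        cfg["n_encoder_layers"] = spec.n_encoder_layers
        config = ModelConfig(**cfg)
        results[spec.name] = cross_validate(
            embeddings, y, config, k=k, seed=seed, folds=folds
        )
    return results


def run_noise_sweep(
    records: Sequence[ProteinRecord],
    labels: Sequence[int],
    ratios: Sequence[float],
    embedder: Callable[[Sequence[ProteinRecord]], EmbeddingSet],
    config: ModelConfig,
    k: int = 5,
    seed: int = 0,
    n_windows: int = 1,
) -> tuple[dict[float, FoldReport], dict[float, dict[str, float]]]:
    """Shuffle-noise robustness sweep.

    For each ratio: perturb the sequences, re-embed (embeddings are cached
    by corpus content digest, so ratio 0 reuses the unperturbed corpus's
    embedding), and cross-validate with the shared fold split. Returns the
    per-ratio fold reports and a summary of mean AUC/AUPR per ratio.
    """
    if any(not (0.0 <= r <= 1.0) for r in ratios):
        raise ParameterError("all ratios must be in [0, 1]")
    y = np.asarray(labels, dtype=int)
    folds = kfold_split(len(records), k, y, seed)
    cache: dict[int, EmbeddingSet] = {}
    reports: dict[float, FoldReport] = {}
    summary: dict[float, dict[str, float]] = {}
    for ratio in ratios:
        perturbed = perturb_corpus(records, NoiseSpec(shuffle_ratio=ratio, seed=seed),
                                   n_windows)
        digest = sequence_digest(perturbed)
        if digest not in cache:
            cache[digest] = embedder(perturbed)
        report = cross_validate(cache[digest], y, config, k=k, seed=seed, folds=folds)
        reports[ratio] = report
        summary[ratio] = {
            "auc": report.aggregate["auc"],
            "aupr": report.aggregate["aupr"],
        }
    return reports, summary
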