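"""Fixed-length numeric embeddings of protein sequences.

Two embedders share one output container:

* :func:`embed_with_plm` — adapter around an external protein language
  model runtime (ESM-style). The runtime is optional; when it cannot be
  imported the adapter fails with an actionable error.
* :func:`embed_synthetic` — a deterministic stand-in used throughout the
  test suite: a hash-derived k-mer-composition signal plus an optional
  label-dependent mean shift and Gaussian noise, fully reproducible and
  independent of batch order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np

from .corpus import ProteinRecord
from .errors import EmbedderUnavailableError, IntegrityError, ParameterError

_EMBED_KMER = 3


@dataclass
class EmbeddingSet:
    """Aligned table of per-sequence feature vectors."""

    ids: list[str]
    matrix: np.ndarray  # (n_samples, num_feature)
    num_feature: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise IntegrityError("embedding matrix must be 2-D")
        if self.matrix.shape != (len(self.ids), self.num_feature):
            raise IntegrityError(
                f"matrix shape {self.matrix.shape} does not match "
                f"({len(self.ids)}, {self.num_feature})"
            )
        if len(set(self.ids)) != len(self.ids):
            raise IntegrityError("duplicate ids in embedding set")
        if not np.all(np.isfinite(self.matrix)):
            raise IntegrityError("non-finite entries in embedding matrix")

    def __len__(self) -> int:
        return len(self.ids)

    def vector(self, rid: str) -> np.ndarray:
        return self.matrix[self.ids.index(rid)]

    def subset(self, ids: Sequence[str]) -> "EmbeddingSet":
        index = {rid: i for i, rid in enumerate(self.ids)}
        rows = [index[r] for r in ids]
        return EmbeddingSet(list(ids), self.matrix[rows], self.num_feature, dict(self.metadata))

    def merge(self, other: "EmbeddingSet") -> "EmbeddingSet":
        if self.num_feature != other.num_feature:
            raise IntegrityError("cannot merge embedding sets of different dimension")
        if set(self.ids) & set(other.ids):
            raise IntegrityError("cannot merge embedding sets with overlapping ids")
        return EmbeddingSet(
            self.ids + other.ids,
            np.vstack([self.matrix, other.matrix]),
            self.num_feature,
            dict(self.metadata),
        )


def _shift_coordinates(num_feature: int) -> np.ndarray:
    """Fixed coordinate subset carrying the class-mean shift.

    Half the coordinates form a contiguous block (spatially localized once
    the vector is reshaped to a grid); the other half are strided across
    the vector (dispersed), so both a convolutional and a global feature
    extractor can see class signal.
    """
    n_shift = max(4, num_feature // 16)
    half = n_shift // 2
    block = np.arange(num_feature // 3, num_feature // 3 + half)
    strided = np.linspace(0, num_feature - 1, n_shift - half, dtype=int)
    return np.unique(np.concatenate([block, strided]))


def _base_signal(sequence: str, num_feature: int) -> np.ndarray:
    """Deterministic k-mer composition hashed into ``num_feature`` bins.

    Counts are normalized by sqrt(number of k-mers) so the composition
    signal has O(1) scale regardless of sequence length; class separability
    is then governed by the class_shift / noise_sd ratio as documented.
    """
    vec = np.zeros(num_feature)
    n_kmers = len(sequence) - _EMBED_KMER + 1
    for i in range(max(0, n_kmers)):
        kmer = sequence[i : i + _EMBED_KMER]
        vec[zlib.crc32(kmer.encode()) % num_feature] += 1.0
    return vec / np.sqrt(max(1, n_kmers))


def embed_synthetic(
    records: Sequence[ProteinRecord],
    num_feature: int = 1280,
    class_shift: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> EmbeddingSet:
    """Deterministic synthetic embedder with controllable class separability.

    Each vector is the sum of a hash-derived 3-mer-composition signal, a
    mean shift of magnitude ``class_shift`` on a fixed coordinate subset
    for positive-labeled records, and Gaussian noise of scale ``noise_sd``.
    The noise stream is derived from ``(seed, sequence)`` so a record's
    vector never depends on its position in the batch, and identical
    sequences map to identical vectors.
    """
    if num_feature < 4:
        raise ParameterError(f"num_feature must be >= 4, got {num_feature}")
    if noise_sd <= 0:
        raise ParameterError(f"noise_sd must be > 0, got {noise_sd}")
    if class_shift < 0:
        raise ParameterError(f"class_shift must be >= 0, got {class_shift}")
    if class_shift > 0 and any(r.label == "unknown" for r in records):
        raise ParameterError("class_shift > 0 requires labeled records")

    shift_idx = _shift_coordinates(num_feature)
    rows = np.empty((len(records), num_feature))
    for i, rec in enumerate(records):
        vec = _base_signal(rec.sequence, num_feature)
        if class_shift > 0 and rec.label == "positive":
            vec[shift_idx] += class_shift
        rng = np.random.default_rng([seed, zlib.crc32(rec.sequence.encode())])
        vec += rng.normal(0.0, noise_sd, num_feature)
        rows[i] = vec
    return EmbeddingSet(
        [r.id for r in records],
        rows,
        num_feature,
        {"embedder": "synthetic", "pooling": "none", "class_shift": class_shift,
         "noise_sd": noise_sd, "seed": seed},
    )


def embed_with_plm(
    records: Sequence[ProteinRecord],
    model_name: str,
    pooling: str = "mean",
    cache: dict | None = None,
) -> EmbeddingSet:
    """Embed sequences with an external protein language model (ESM family).

    Per-residue representations from the final layer are pooled to one
    vector per sequence (``mean`` over residues, or the ``cls``/BOS token).
    Sequences longer than the model context are truncated with a warning.
    Results are memoized in ``cache`` (keyed by sequence) when provided.

    Raises :class:`EmbedderUnavailableError` when no PLM runtime is
    importable; :func:`embed_synthetic` is the self-contained alternative.
    """
    if pooling not in ("mean", "cls"):
        raise ParameterError(f"pooling must be 'mean' or 'cls', got {pooling!r}")
    try:
        import esm  # type: ignore
        import torch  # type: ignore
    except ImportError as exc:
        raise EmbedderUnavailableError(
            f"protein language model runtime for {model_name!r} is not installed "
            "(requires the 'fair-esm' and 'torch' packages); use "
            "protfuse.embedding.embed_synthetic for a self-contained embedder"
        ) from exc

    import warnings

    model, alphabet = esm.pretrained.load_model_and_alphabet(model_name)
    model.eval()
    converter = alphabet.get_batch_converter()
    n_layers = model.num_layers
    max_len = 1022  # ESM positional-embedding budget minus BOS/EOS
    cache = cache if cache is not None else {}
    rows = []
    with torch.no_grad():
        for rec in records:
            key = (model_name, pooling, rec.sequence)
            if key in cache:
                rows.append(cache[key])
                continue
            seq = rec.sequence
            if len(seq) > max_len:
                warnings.warn(f"{rec.id}: truncating {len(seq)} aa to model context {max_len}")
                seq = seq[:max_len]
            _, _, toks = converter([(rec.id, seq)])
            reps = model(toks, repr_layers=[n_layers])["representations"][n_layers][0]
            if pooling == "mean":
                vec = reps[1 : len(seq) + 1].mean(dim=0)
            else:
                vec = reps[0]
            vec = vec.cpu().numpy().astype(np.float64)
            cache[key] = vec
            rows.append(vec)
    matrix = np.vstack(rows)
    return EmbeddingSet(
        [r.id for r in records],
        matrix,
        matrix.shape[1],
        {"embedder": model_name, "pooling": pooling},
    )


def save_embeddings(eset: EmbeddingSet, path) -> None:
    """Write an :class:`EmbeddingSet` to an HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("ids", data=np.array(eset.ids, dtype=h5py.string_dtype()))
        fh.create_dataset("matrix", data=eset.matrix)
        fh.attrs["num_feature"] = eset.num_feature
        for key in ("embedder", "pooling"):
            fh.attrs[key] = str(eset.metadata.get(key, ""))


def load_embeddings(path) -> EmbeddingSet:
    """Read an HDF5 embedding container, validating its internal consistency."""
    try:
        with h5py.File(path, "r") as fh:
            ids = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["ids"][...]]
            matrix = fh["matrix"][...]
            num_feature = int(fh.attrs["num_feature"])
            metadata = {k: fh.attrs[k] for k in ("embedder", "pooling") if k in fh.attrs}
    except (OSError, KeyError) as exc:
        raise IntegrityError(f"cannot read embedding container {path}: {exc}") from exc
    if matrix.ndim != 2 or matrix.shape[1] != num_feature:
        raise IntegrityError(
            f"{path}: matrix width {matrix.shape} does not match num_feature={num_feature}"
        )
    return EmbeddingSet(ids, matrix, num_feature, metadata)


class Standardizer:
    """Per-coordinate zero-mean / unit-variance scaling, fit on training data
    only so no fold statistics leak into evaluation."""

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant coordinates pass through centred
        self.sd_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ParameterError("Standardizer not fitted")
        return (np.asarray(X, dtype=np.float64) - self.mean_) / self.sd_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
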