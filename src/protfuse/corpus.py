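"""Labeled protein-sequence corpus assembly.

Reads FASTA, canonicalizes residues, removes redundant (high-identity)
sequences with a greedy longest-first clustering akin to CD-HIT, and draws
balanced negative samples from a background pool.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import ParameterError, ParseError, SequenceRejectedError

#: The 20 canonical amino acids.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: k-mer size used by the fast identity estimate.
IDENTITY_KMER = 5


@dataclass(frozen=True)
class ProteinRecord:
    """One labeled protein sequence."""

    id: str
    sequence: str
    label: str = "unknown"  # positive | negative | unknown
    source: str = ""

    def __post_init__(self):
        if self.label not in ("positive", "negative", "unknown"):
            raise ParameterError(f"invalid label {self.label!r} for record {self.id!r}")


@dataclass
class CorpusSummary:
    """Bookkeeping counts produced by corpus assembly."""

    n_positive: int = 0
    n_negative: int = 0
    n_removed_redundant: int = 0
    n_corrected: int = 0

    def __post_init__(self):
        for name in ("n_positive", "n_negative", "n_removed_redundant", "n_corrected"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


def read_fasta(path, on_duplicate: str = "error") -> list[ProteinRecord]:
    """Read a FASTA file into ``ProteinRecord`` objects with label ``unknown``.

    Residues are upper-cased; entry order is preserved.

    Parameters
    ----------
    path:
        FASTA file path.
    on_duplicate:
        ``"error"`` raises on a repeated id; ``"suffix"`` disambiguates by
        appending ``.1``, ``.2`` ... to later occurrences.
    """
    if on_duplicate not in ("error", "suffix"):
        raise ParameterError("on_duplicate must be 'error' or 'suffix'")
    path = Path(path)
    text = path.read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), None)
    if first is None:
        raise ParseError(f"{path}: empty FASTA file")
    if not first.startswith(">"):
        lineno = next(
            i for i, ln in enumerate(text.splitlines(), 1) if ln.strip()
        )
        raise ParseError(f"{path}:{lineno}: expected FASTA header '>', got {first[:30]!r}")

    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if not rid:
            raise ParseError(f"{path}: FASTA entry with empty id")
        if rid in seen:
            if on_duplicate == "error":
                raise ParseError(f"{path}: duplicate FASTA id {rid!r}")
            seen[rid] += 1
            rid = f"{rid}.{seen[rid]}"
        else:
            seen[rid] = 0
        records.append(ProteinRecord(id=rid, sequence=str(entry.seq).upper()))
    if not records:
        raise ParseError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_labels(path) -> dict[str, str]:
    """Read a two-column (id, label) TSV."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            labels[row[0]] = row[1]
    return labels


def write_labels(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{rec.label}\n")


def clean_sequence(record: ProteinRecord, policy: str = "substitute-X") -> tuple[ProteinRecord, int]:
    """Canonicalize a sequence, handling non-standard residue codes.

    Policies: ``substitute-X`` replaces each non-canonical residue with ``X``
    (preserving length, the default so truncation offsets stay meaningful);
    ``strip`` deletes them; ``drop`` rejects any record containing one.

    Returns the cleaned record and the number of corrected positions.
    Raises :class:`SequenceRejectedError` if the sequence would become empty
    (or under ``drop`` when any non-canonical residue is present).
    """
    if policy not in ("drop", "substitute-X", "strip"):
        raise ParameterError(f"unknown cleaning policy {policy!r}")
    seq = record.sequence.upper()
    if not seq:
        raise SequenceRejectedError(f"{record.id}: empty sequence")
    bad = [i for i, ch in enumerate(seq) if ch not in CANONICAL_RESIDUES]
    if not bad:
        return (replace(record, sequence=seq), 0)
    if policy == "drop":
        raise SequenceRejectedError(
            f"{record.id}: {len(bad)} non-canonical residue(s) under policy 'drop'"
        )
    if policy == "substitute-X":
        chars = list(seq)
        for i in bad:
            chars[i] = "X"
        return (replace(record, sequence="".join(chars)), len(bad))
    # strip
    kept = "".join(ch for ch in seq if ch in CANONICAL_RESIDUES)
    if not kept:
        raise SequenceRejectedError(
            f"{record.id}: sequence empty after stripping non-canonical residues"
        )
    return (replace(record, sequence=kept), len(bad))


def clean_corpus(
    records: Sequence[ProteinRecord], policy: str = "substitute-X"
) -> tuple[list[ProteinRecord], int, list[tuple[str, str]]]:
    """Clean every record; returns (cleaned, n_corrected_records, rejections)."""
    cleaned, n_corrected, rejected = [], 0, []
    for rec in records:
        try:
            out, n_bad = clean_sequence(rec, policy)
        except SequenceRejectedError as exc:
            rejected.append((rec.id, str(exc)))
            continue
        cleaned.append(out)
        n_corrected += int(n_bad > 0)
    return cleaned, n_corrected, rejected


def _kmer_set(seq: str, k: int = IDENTITY_KMER) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_identity(a: str, b: str, k: int = IDENTITY_KMER) -> float:
    """Fast identity estimate: shared-k-mer fraction over the shorter sequence.

    Falls back to exact string equality when the shorter sequence has no
    k-mers. This approximates (from below) alignment identity for sequences
    whose differences are localized, which is how near-duplicate database
    entries typically differ.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if len(short) - k + 1 <= 0:
        return 1.0 if short == long_ else 0.0
    short_kmers = _kmer_set(short, k)
    shared = len(short_kmers & _kmer_set(long_, k))
    return shared / len(short_kmers)


def redundancy_filter(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.9,
    k: int = IDENTITY_KMER,
) -> tuple[list[ProteinRecord], CorpusSummary]:
    """Greedy longest-first redundancy removal (CD-HIT style).

    Records are processed longest-first (ties broken by id). Each record
    joins the first existing cluster whose representative shares at least
    ``identity_threshold`` k-mer identity; otherwise it founds a new
    cluster. Cluster representatives are returned.
    """
    if not records:
        raise ParameterError("redundancy_filter requires at least one record")
    if not (0.0 < identity_threshold <= 1.0):
        raise ParameterError(f"identity_threshold must be in (0, 1], got {identity_threshold}")

    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[ProteinRecord] = []
    rep_kmers: list[frozenset] = []
    removed = 0
    for rec in order:
        joined = False
        rec_kmers = _kmer_set(rec.sequence, k)
        for rep, rkm in zip(reps, rep_kmers):
            if not rec_kmers:
                ident = 1.0 if rec.sequence == rep.sequence else 0.0
            else:
                # rec is the shorter (or equal) sequence by processing order
                ident = len(rec_kmers & rkm) / len(rec_kmers)
            if ident >= identity_threshold:
                joined = True
                removed += 1
                break
        if not joined:
            reps.append(rec)
            rep_kmers.append(rec_kmers)

    summary = CorpusSummary(
        n_positive=sum(r.label == "positive" for r in reps),
        n_negative=sum(r.label == "negative" for r in reps),
        n_removed_redundant=removed,
    )
    return reps, summary


def sample_negatives(
    pool: Sequence[ProteinRecord],
    positives: Sequence[ProteinRecord],
    n: int,
    seed: int,
) -> list[ProteinRecord]:
    """Draw ``n`` background records uniformly without replacement.

    Excludes any pool record sharing an id or an exact sequence with a
    positive. The draw is reproducible from ``seed`` and independent of
    pool ordering.
    """
    pos_ids = {r.id for r in positives}
    pos_seqs = {r.sequence for r in positives}
    eligible = sorted(
        (r for r in pool if r.id not in pos_ids and r.sequence not in pos_seqs),
        key=lambda r: r.id,
    )
    if len(eligible) < n:
        raise ParameterError(
            f"negative pool too small: need {n}, have {len(eligible)} "
            f"after excluding positives (shortfall {n - len(eligible)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [replace(eligible[i], label="negative") for i in sorted(idx)]


def assemble_corpus(
    positives: Sequence[ProteinRecord],
    pool: Sequence[ProteinRecord],
    identity_threshold: float = 0.9,
    policy: str = "substitute-X",
    filter_negatives: bool = True,
    seed: int = 0,
) -> tuple[list[ProteinRecord], CorpusSummary]:
    """Full curation pipeline: clean, deduplicate positives, sample balanced
    negatives (optionally deduplicated too), and return the merged corpus.
    """
    pos_clean, n_corr_pos, _ = clean_corpus(positives, policy)
    pos_clean = [replace(r, label="positive") for r in pos_clean]
    pos_kept, pos_summary = redundancy_filter(pos_clean, identity_threshold)

    pool_clean, n_corr_pool, _ = clean_corpus(pool, policy)
    negatives = sample_negatives(pool_clean, pos_kept, len(pos_kept), seed)
    n_removed_neg = 0
    if filter_negatives:
        negatives, neg_summary = redundancy_filter(negatives, identity_threshold)
        n_removed_neg = neg_summary.n_removed_redundant
        # top up so the corpus stays balanced after deduplication
        while len(negatives) < len(pos_kept):
            extra = sample_negatives(
                pool_clean, pos_kept + negatives, len(pos_kept) - len(negatives), seed + 1
            )
            negatives = redundancy_filter(negatives + extra, identity_threshold)[0]

    summary = CorpusSummary(
        n_positive=len(pos_kept),
        n_negative=len(negatives),
        n_removed_redundant=pos_summary.n_removed_redundant + n_removed_neg,
        n_corrected=n_corr_pos + n_corr_pool,
    )
    return pos_kept + negatives, summary


def sequence_digest(records: Sequence[ProteinRecord]) -> int:
    """Order-sensitive content digest of a corpus (for embedding caches)."""
    h = 0
    for rec in records:
        h = zlib.crc32(f"{rec.id}\x00{rec.sequence}\x00{rec.label}\n".encode(), h)
    return h
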