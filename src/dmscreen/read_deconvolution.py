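"""Amplicon read deconvolution: merge pairs, call codon variants, tally counts.

A deliberately simple, fully documented re-implementation of a pooled-ORF
screen deconvolution stage: paired reads are quality-trimmed and merged on
their best exact overlap, anchored to the reference by exact k-mer seeding
with ungapped extension, mismatches are grouped into codons, and each read
is classified as wild-type, a designed variant, an unintended single-codon
variant, a multi-codon variant, unalignable, or low-quality.  Counts are
conserved: every input read lands in exactly one row of the counts matrix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .library_design import LibraryDesign
from .sequence_core import ORFSequence, reverse_complement

__all__ = [
    "ReadPair",
    "ReadCall",
    "CountsMatrix",
    "DeconvolutionParams",
    "merge_and_trim",
    "call_read",
    "tally",
    "read_fastq_pairs",
]

RESERVED_ROWS = ["WT", "UNINTENDED", "MULTI", "UNALIGNABLE", "LOW_QUALITY"]

STATUS_TO_ROW = {
    "wild_type": "WT",
    "unintended_variant": "UNINTENDED",
    "multi_variant": "MULTI",
    "unalignable": "UNALIGNABLE",
    "low_quality": "LOW_QUALITY",
}


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: tuple[int, ...]
    qual2: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError("sequence/quality length mismatch")


@dataclass(frozen=True)
class ReadCall:
    read_id: str
    status: str
    variant_id: str | None = None

    def __post_init__(self) -> None:
        if (self.status == "designed_variant") != (self.variant_id is not None):
            raise ValueError("variant_id present iff status is designed_variant")


@dataclass(frozen=True)
class DeconvolutionParams:
    """Caller parameters; defaults permissive enough for a 3-nt codon change
    plus sparse sequencing errors."""

    min_qual: int = 20
    min_overlap: int = 20
    seed_k: int = 20
    max_mismatch: int = 6


def _trim_3prime(seq: str, qual: tuple[int, ...], min_qual: int) -> tuple[str, tuple[int, ...]]:
    end = len(seq)
    while end > 0 and qual[end - 1] < min_qual:
        end -= 1
    return seq[:end], qual[:end]


def merge_and_trim(
    pair: ReadPair, min_qual: int = 20, min_overlap: int = 20
) -> tuple[str, tuple[int, ...]] | None:
    """Merge a read pair into one consensus read, or None for low quality.

    Mate 2 is reverse-complemented into mate-1 orientation.  After 3'
    quality trimming, the mates are merged at their best exact-overlap
    offset of length >= ``min_overlap`` (most identities among overlaps
    with zero disagreement; if none is disagreement-free the highest
    identity wins and disagreements resolve to the higher-quality base,
    mate 1 winning ties).  A mean consensus quality below ``min_qual``
    or no acceptable overlap yields None.
    """
    s1, q1 = _trim_3prime(pair.seq1, pair.qual1, min_qual)
    s2r = reverse_complement(pair.seq2) if pair.seq2 else ""
    q2r = pair.qual2[::-1]
    # trim mate2's original 3' end = left end after reverse complement
    start = 0
    while start < len(s2r) and q2r[start] < min_qual:
        start += 1
    s2, q2 = s2r[start:], q2r[start:]
    if not s1 or not s2:
        return None

    best_key, off, ov = None, -1, -1
    for cand_off in range(len(s1) - min_overlap + 1):
        cand_ov = min(len(s1) - cand_off, len(s2))
        if cand_ov < min_overlap:
            continue
        n_match = sum(
            a == b for a, b in zip(s1[cand_off : cand_off + cand_ov], s2[:cand_ov])
        )
        key = (n_match == cand_ov, n_match / cand_ov, -cand_off)
        if best_key is None or key > best_key:
            best_key, off, ov = key, cand_off, cand_ov
    # no acceptable overlap, or best overlap too discordant to merge
    if best_key is None or best_key[1] < 0.8:
        return None

    cons: list[str] = list(s1[:off])
    cq: list[int] = list(q1[:off])
    for i in range(ov):
        a, qa = s1[off + i], q1[off + i]
        b, qb = s2[i], q2[i]
        if a == b:
            cons.append(a)
            cq.append(max(qa, qb))
        elif qa >= qb:
            cons.append(a)
            cq.append(qa)
        else:
            cons.append(b)
            cq.append(qb)
    cons.extend(s2[ov:])
    cq.extend(q2[ov:])
    consensus, cqual = "".join(cons), tuple(cq)
    if np.mean(cqual) < min_qual:
        return None
    return consensus, cqual


@lru_cache(maxsize=8)
def _kmer_index(ref: str, k: int) -> dict[str, int]:
    index: dict[str, int] = {}
    for i in range(len(ref) - k + 1):
        index.setdefault(ref[i : i + k], i)
    return index


def _seed_anchor(read: str, ref: str, k: int) -> int | None:
    """Reference offset of the read's start via the first exact k-mer hit."""
    kmer_index = _kmer_index(ref, k)
    for j in range(0, len(read) - k + 1):
        hit = kmer_index.get(read[j : j + k])
        if hit is not None:
            start = hit - j
            if 0 <= start <= len(ref) - len(read):
                return start
    return None


def call_read(
    read: str,
    orf: ORFSequence,
    design: LibraryDesign,
    max_mismatch: int = 6,
    seed_k: int = 20,
    read_id: str = "read",
) -> ReadCall:
    """Classify one consensus read against the reference and the design.

    The read is anchored by exact k-mer seeding and extended without gaps;
    mismatches are grouped by reference codon.  Zero changed codons is
    wild-type; one changed codon matching a designed alt codon is that
    designed variant; one unmatched changed codon is unintended; two or
    more changed codons is multi-variant.  No anchor, an out-of-reference
    placement, or too many mismatches is unalignable.
    """
    ref = orf.nucleotides
    if not read or len(read) > len(ref):
        return ReadCall(read_id, "unalignable")
    start = _seed_anchor(read, ref, seed_k)
    if start is None:
        return ReadCall(read_id, "unalignable")
    mismatches = [
        start + i for i, (a, b) in enumerate(zip(read, ref[start : start + len(read)]))
        if a != b
    ]
    if len(mismatches) > max_mismatch:
        return ReadCall(read_id, "unalignable")
    changed_codons = sorted({pos // 3 for pos in mismatches})
    if not changed_codons:
        return ReadCall(read_id, "wild_type")
    if len(changed_codons) > 1:
        return ReadCall(read_id, "multi_variant")
    ci = changed_codons[0]
    codon_number = orf.codon_offset + ci
    observed = list(ref[3 * ci : 3 * ci + 3])
    for pos in mismatches:
        observed[pos - 3 * ci] = read[pos - start]
    observed_codon = "".join(observed)
    variant_id = design.alt_index().get((codon_number, observed_codon))
    if variant_id is not None:
        return ReadCall(read_id, "designed_variant", variant_id)
    return ReadCall(read_id, "unintended_variant")


class CountsMatrix:
    """Variant x sample integer counts with conserved per-sample totals.

    Rows are all variant ids of a design plus the reserved rows WT,
    UNINTENDED, MULTI, UNALIGNABLE and LOW_QUALITY; the column sum of every
    sample equals its total input reads.
    """

    def __init__(self, counts: pd.DataFrame, totals: pd.Series):
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        sums = counts.sum(axis=0)
        if not (sums == totals.loc[counts.columns]).all():
            raise ValueError("column sums do not match per-sample totals")
        self.counts = counts.astype(np.int64)
        self.totals = totals.loc[counts.columns].astype(np.int64)

    @classmethod
    def empty(cls, variant_ids: list[str], sample_ids: list[str]) -> "CountsMatrix":
        idx = list(variant_ids) + RESERVED_ROWS
        df = pd.DataFrame(0, index=idx, columns=list(sample_ids), dtype=np.int64)
        return cls(df, df.sum(axis=0))

    @property
    def variant_ids(self) -> list[str]:
        return [i for i in self.counts.index if i not in RESERVED_ROWS]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def assigned_total(self, sample: str) -> int:
        """Reads assigned to the library: WT plus designed variants."""
        discard = [r for r in RESERVED_ROWS if r != "WT"]
        return int(self.counts[sample].drop(discard).sum())

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "variant_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountsMatrix":
        df = pd.read_csv(path, sep="\t", index_col="variant_id")
        missing = [r for r in RESERVED_ROWS if r not in df.index]
        if missing:
            raise ValueError(f"counts table missing reserved rows: {missing}")
        return cls(df, df.sum(axis=0))


def tally(
    pairs_per_sample: dict[str, list[ReadPair]],
    orf: ORFSequence,
    design: LibraryDesign,
    params: DeconvolutionParams = DeconvolutionParams(),
) -> CountsMatrix:
    """Count designed variants per sample from paired reads.

    Deterministic given its inputs; the per-sample column sum always equals
    the number of input read pairs.
    """
    variant_ids = [v.variant_id for v in design.variants]
    mat = CountsMatrix.empty(variant_ids, list(pairs_per_sample))
    counts = mat.counts
    for sample, pairs in pairs_per_sample.items():
        for pair in pairs:
            merged = merge_and_trim(pair, params.min_qual, params.min_overlap)
            if merged is None:
                counts.loc["LOW_QUALITY", sample] += 1
                continue
            call = call_read(
                merged[0], orf, design, params.max_mismatch, params.seed_k, pair.id
            )
            row = call.variant_id if call.status == "designed_variant" else STATUS_TO_ROW[call.status]
            counts.loc[row, sample] += 1
    return CountsMatrix(counts, counts.sum(axis=0))


def _open_maybe_gz(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(fastq1, fastq2) -> list[ReadPair]:
    """Load paired FASTQ files (plain or gzipped) into ReadPair objects."""
    from Bio import SeqIO

    pairs = []
    with _open_maybe_gz(fastq1) as f1, _open_maybe_gz(fastq2) as f2:
        for r1, r2 in zip(
            SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq"), strict=True
        ):
            pairs.append(
                ReadPair(
                    id=r1.id,
                    seq1=str(r1.seq).upper(),
                    seq2=str(r2.seq).upper(),
                    qual1=tuple(r1.letter_annotations["phred_quality"]),
                    qual2=tuple(r2.letter_annotations["phred_quality"]),
                )
            )
    return pairs
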