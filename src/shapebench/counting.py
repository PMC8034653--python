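"""Mutational-profiling (MaP) read counting.

Converts aligned reads into per-base mutation counts, coverage and
frequencies.  Counting semantics: every mutation event in a read is
counted (mutational profiling records multiple modification sites per
cDNA); mismatches are called against the reference sequence directly;
deletions count once per deleted reference position and, when ambiguous
within a repeat, are re-aligned to their rightmost equivalent placement;
insertions are charged to the reference position immediately 3' of the
insertion site.  At most one event per read per position, so
``counts <= coverage`` holds everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .formats import AlignedRead

logger = logging.getLogger(__name__)

__all__ = [
    "MutationProfile",
    "ReadBatch",
    "RawRead",
    "filter_reads",
    "count_mutations",
    "median_frequency",
    "median_frequency_ratio",
]

_OP_CODE = {"M": 0, "=": 0, "X": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6}
_OP_CHAR = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S", 5: "H", 6: "P"}


@dataclass
class MutationProfile:
    """Per-base mutation counts, coverage and frequencies for one transcript.

    ``frequency`` is counts/coverage where coverage >= ``min_coverage`` and
    NaN (undefined) elsewhere.  Arrays are 0-based internally; the table
    writers expose 1-based positions.
    """

    transcript_id: str
    sequence: str
    counts: np.ndarray
    coverage: np.ndarray
    min_coverage: int = 100
    n_skipped_reads: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if not (len(self.counts) == len(self.coverage) == len(self.sequence)):
            raise ValueError("counts, coverage and sequence lengths disagree")
        if np.any(self.counts > self.coverage):
            raise ValueError("mutation count exceeds coverage")
        if np.any(self.counts < 0) or np.any(self.coverage < 0):
            raise ValueError("negative counts or coverage")

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def frequency(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.counts / self.coverage
        f[self.coverage < self.min_coverage] = np.nan
        return f


@dataclass
class ReadBatch:
    """Column-packed alignments for one reference; the fast path into
    :func:`count_mutations`.  ``starts`` are 0-based; CIGAR runs use the
    integer op codes of :mod:`shapebench._kernels`."""

    rname: str
    reference_length: int
    starts: np.ndarray
    seqs: np.ndarray
    seq_off: np.ndarray
    cig_ops: np.ndarray
    cig_lens: np.ndarray
    cig_off: np.ndarray
    quals: np.ndarray  # flattened, aligned with seqs

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def from_reads(cls, reads: list[AlignedRead], rname: str,
                   reference_length: int) -> "ReadBatch":
        starts = np.array([r.pos - 1 for r in reads], dtype=np.int64)
        seq_off = np.zeros(len(reads) + 1, dtype=np.int64)
        cig_off = np.zeros(len(reads) + 1, dtype=np.int64)
        for k, r in enumerate(reads):
            seq_off[k + 1] = seq_off[k] + len(r.seq)
            cig_off[k + 1] = cig_off[k] + len(r.cigar)
        seqs = np.empty(seq_off[-1], dtype=np.uint8)
        quals = np.empty(seq_off[-1], dtype=np.uint8)
        cig_ops = np.empty(cig_off[-1], dtype=np.int8)
        cig_lens = np.empty(cig_off[-1], dtype=np.int32)
        for k, r in enumerate(reads):
            seqs[seq_off[k]:seq_off[k + 1]] = np.frombuffer(r.seq.encode(), dtype=np.uint8)
            quals[seq_off[k]:seq_off[k + 1]] = r.qual
            for c, (op, ln) in enumerate(r.cigar):
                cig_ops[cig_off[k] + c] = _OP_CODE[op]
                cig_lens[cig_off[k] + c] = ln
        return cls(rname=rname, reference_length=reference_length, starts=starts,
                   seqs=seqs, seq_off=seq_off, cig_ops=cig_ops, cig_lens=cig_lens,
                   cig_off=cig_off, quals=quals)

    def to_records(self, qname_prefix: str = "read") -> list[AlignedRead]:
        out = []
        for k in range(len(self)):
            s0, s1 = self.seq_off[k], self.seq_off[k + 1]
            c0, c1 = self.cig_off[k], self.cig_off[k + 1]
            cigar = [(_OP_CHAR[int(self.cig_ops[c])], int(self.cig_lens[c]))
                     for c in range(c0, c1)]
            out.append(AlignedRead(
                qname=f"{qname_prefix}_{k}", flag=0, rname=self.rname,
                pos=int(self.starts[k]) + 1, mapq=60, cigar=cigar,
                seq=self.seqs[s0:s1].tobytes().decode(),
                qual=self.quals[s0:s1].copy(),
            ))
        return out

    def to_sam(self, qname_prefix: str = "read") -> str:
        from .formats import write_sam

        return write_sam(self.to_records(qname_prefix), self.rname,
                         self.reference_length)


# ---------------------------------------------------------------------------
# Raw-read quality filtering

@dataclass
class RawRead:
    name: str
    seq: str
    qual: np.ndarray  # Phred scores


def filter_reads(records, qmin: int = 20):
    """Trim terminal Ns and terminal low-quality bases, drop internal-N reads.

    Both ends are trimmed while the terminal base is an N or has
    Phred < ``qmin``; any read still containing an internal N is discarded,
    as are reads left empty.  Returns (kept_records, stats) where stats
    counts trimmed bases and dropped reads.
    """
    kept = []
    stats = {"input": 0, "kept": 0, "dropped_internal_n": 0,
             "dropped_empty": 0, "bases_trimmed": 0}
    for rec in records:
        stats["input"] += 1
        seq, qual = rec.seq, np.asarray(rec.qual)
        a, b = 0, len(seq)
        while a < b and (seq[a] == "N" or qual[a] < qmin):
            a += 1
        while b > a and (seq[b - 1] == "N" or qual[b - 1] < qmin):
            b -= 1
        stats["bases_trimmed"] += len(seq) - (b - a)
        if b <= a:
            stats["dropped_empty"] += 1
            continue
        trimmed_seq = seq[a:b]
        if "N" in trimmed_seq:
            stats["dropped_internal_n"] += 1
            continue
        kept.append(RawRead(name=rec.name, seq=trimmed_seq, qual=qual[a:b]))
        stats["kept"] += 1
    return kept, stats


# ---------------------------------------------------------------------------
# Counting

def count_mutations(alignments, reference_sequence: str, *,
                    transcript_id: str = "transcript", qmin: int = 20,
                    realign_deletions: bool = True, count_insertions: bool = True,
                    min_coverage: int = 100) -> MutationProfile:
    """Count mutation events and coverage per reference position.

    ``alignments`` may be a :class:`ReadBatch` or an iterable of
    :class:`AlignedRead` (only primary, mapped records are counted).
    Reads whose alignment extends past the reference end are skipped and
    reported via ``n_skipped_reads``.
    """
    reference_sequence = reference_sequence.upper().replace("T", "U")
    ref = np.frombuffer(reference_sequence.encode(), dtype=np.uint8)
    n = len(ref)
    if isinstance(alignments, ReadBatch):
        batch = alignments
    else:
        usable = [r for r in alignments if r.is_mapped and r.is_primary]
        batch = ReadBatch.from_reads(usable, transcript_id, n)
    counts = np.zeros(n, dtype=np.int64)
    coverage = np.zeros(n, dtype=np.int64)
    skipped = _kernels.count_kernel(
        ref, batch.starts, batch.cig_ops, batch.cig_lens, batch.cig_off,
        batch.seqs, batch.seq_off, batch.quals,
        qmin, realign_deletions, count_insertions, counts, coverage,
    )
    if skipped:
        logger.warning("count_mutations: skipped %d read(s) extending past the reference", skipped)
    return MutationProfile(transcript_id=transcript_id, sequence=reference_sequence,
                           counts=counts, coverage=coverage,
                           min_coverage=min_coverage, n_skipped_reads=int(skipped))


# ---------------------------------------------------------------------------
# Summary statistics

def median_frequency(profile: MutationProfile, region=None) -> float:
    """Median of defined per-base frequencies, optionally over a 1-based
    inclusive (start, end) region."""
    f = profile.frequency
    if region is not None:
        start, end = region
        f = f[start - 1:end]
    f = f[~np.isnan(f)]
    if f.size == 0:
        raise ValueError("no positions with defined frequency in region")
    return float(np.median(f))


def median_frequency_ratio(profile_a: MutationProfile, profile_b: MutationProfile) -> float:
    """Ratio of median frequencies (not the median of ratios), computed over
    positions where both profiles define a frequency."""
    if profile_a.n != profile_b.n:
        raise ValueError("profiles have different lengths")
    fa, fb = profile_a.frequency, profile_b.frequency
    both = ~np.isnan(fa) & ~np.isnan(fb)
    if not both.any():
        raise ValueError("no positions with defined frequency in both profiles")
    med_b = float(np.median(fb[both]))
    if med_b == 0:
        raise ValueError("median of denominator profile is zero")
    return float(np.median(fa[both])) / med_b
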