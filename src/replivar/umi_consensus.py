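"""UMI family grouping and consensus collapsing.

PCR copies of one input ccfDNA molecule share an 8-mer unique molecular
identifier (UMI), an unclipped alignment start and an orientation.  Reads
are partitioned into families by exact equality of that key, and each
family is collapsed column-by-column: a column whose predominant base
exceeds 2/3 concordance yields that base with the maximum supporting
quality, anything else yields N at quality zero.  Consensus reads backed
by at least two PCR copies (family size >= 2) are what the caller sees —
this is the first error-suppression stage of the pipeline.

Families are single-strand: adapters carry a single UMI, so no duplex
pairing is attempted, and mates collapse independently under their own
start/orientation keys.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import dna

#: a column passes when predominant-base count / coverage > this fraction;
#: exact 2/3 agreement passes (2/3 > 0.66), exact 66/100 does not.
DEFAULT_CONCORDANCE = 0.66


@dataclass(frozen=True)
class AlignedRead:
    """A single aligned read with its UMI, in encoded-base form."""

    chrom: str
    unclipped_start: int
    umi: str
    bases: np.ndarray  # uint8 codes, see replivar.dna
    quals: np.ndarray  # int16, same length
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals length mismatch")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.unclipped_start, self.umi, self.is_reverse)


@dataclass
class UmiFamily:
    """All reads sharing one (chrom, unclipped start, UMI, orientation)."""

    key: tuple
    members: list[AlignedRead]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusRead:
    """The collapsed consensus of one UMI family."""

    chrom: str
    start: int
    bases: np.ndarray
    quals: np.ndarray
    family_size: int
    umi: str = ""
    is_reverse: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.bases)


def group_families(reads: Iterable[AlignedRead]) -> list[UmiFamily]:
    """Partition reads into UMI families by exact key equality.

    No fuzzy matching: a one-base shift in unclipped start or any UMI
    mismatch opens a new family.
    """
    buckets: dict[tuple, list[AlignedRead]] = defaultdict(list)
    for read in reads:
        buckets[read.key].append(read)
    return [UmiFamily(key=k, members=v) for k, v in buckets.items()]


def consensus_base(
    column: Sequence[tuple[int, int]], concordance: float = DEFAULT_CONCORDANCE
) -> tuple[int, int]:
    """Collapse one (base, qual) column to its consensus (base, qual).

    The predominant base wins with the *maximum* quality among its
    supporting reads when its fraction strictly exceeds ``concordance``;
    otherwise the column is ambiguous and yields (N, 0).  A tie for
    predominant base can never exceed 2/3 and therefore always yields N.
    """
    if not column:
        raise ValueError("empty column")
    counts = np.zeros(5, dtype=np.int64)
    best_q = np.zeros(5, dtype=np.int64)
    for base, qual in column:
        counts[base] += 1
        if qual > best_q[base]:
            best_q[base] = qual
    top = int(np.argmax(counts))
    # integer comparison keeps the 2/3 boundary exact for any concordance
    # expressible as a ratio of small integers (0.66 -> 33/50)
    if counts[top] > concordance * len(column):
        return top, int(best_q[top])
    return dna.N, 0


def collapse_family(
    family: UmiFamily, concordance: float = DEFAULT_CONCORDANCE
) -> ConsensusRead:
    """Collapse a family into one consensus read over the union footprint.

    Positions covered by only a subset of members are decided by the
    covering members alone.  A family of one returns the read unchanged.
    """
    chrom, start0, umi, is_rev = family.key
    members = family.members
    starts = np.array([m.unclipped_start for m in members])
    ends = np.array([m.unclipped_start + len(m.bases) for m in members])
    span_start = int(starts.min())
    span_end = int(ends.max())
    length = span_end - span_start

    if len(members) == 1:
        m = members[0]
        return ConsensusRead(chrom, span_start, m.bases.copy(), m.quals.copy(),
                             1, umi, is_rev)

    counts = np.zeros((length, 5), dtype=np.int32)
    best_q = np.zeros((length, 5), dtype=np.int16)
    for m in members:
        off = m.unclipped_start - span_start
        idx = np.arange(off, off + len(m.bases))
        np.add.at(counts, (idx, m.bases), 1)
        np.maximum.at(best_q, (idx, m.bases), m.quals)
    cov = counts.sum(axis=1)
    top = counts.argmax(axis=1)
    top_counts = counts[np.arange(length), top]
    # strict > on integers: top_count / cov > concordance
    ok = top_counts > concordance * cov
    bases = np.where(ok, top, dna.N).astype(np.uint8)
    quals = np.where(ok, best_q[np.arange(length), top], 0).astype(np.int16)
    return ConsensusRead(chrom, span_start, bases, quals, len(members), umi, is_rev)


def collapse_families(
    families: Iterable[UmiFamily], concordance: float = DEFAULT_CONCORDANCE
) -> list[ConsensusRead]:
    """Collapse many families, batching same-shape families through numpy.

    Families whose members all share one footprint (the common case for
    fixed-length fragments) are stacked into (n_families, size, length)
    arrays and collapsed in one vectorized pass per (size, length) batch;
    ragged families fall back to :func:`collapse_family`.  Output order
    follows input order.
    """
    families = list(families)
    out: list[ConsensusRead | None] = [None] * len(families)
    batches: dict[tuple[int, int], list[int]] = defaultdict(list)
    for i, fam in enumerate(families):
        if fam.size == 1:
            out[i] = collapse_family(fam, concordance)
            continue
        lens = {len(m.bases) for m in fam.members}
        starts = {m.unclipped_start for m in fam.members}
        if len(lens) == 1 and len(starts) == 1:
            batches[(fam.size, lens.pop())].append(i)
        else:
            out[i] = collapse_family(fam, concordance)

    for (size, length), idxs in batches.items():
        X = np.empty((len(idxs), size, length), dtype=np.uint8)
        Q = np.empty((len(idxs), size, length), dtype=np.int16)
        for row, i in enumerate(idxs):
            for j, m in enumerate(families[i].members):
                X[row, j] = m.bases
                Q[row, j] = m.quals
        counts = np.stack([(X == b).sum(axis=1) for b in range(5)], axis=-1)
        top = counts.argmax(axis=-1)  # (n, length)
        top_counts = np.take_along_axis(counts, top[..., None], axis=-1)[..., 0]
        ok = top_counts > concordance * size
        qual_sup = np.where(X == top[:, None, :], Q, -1).max(axis=1)
        bases = np.where(ok, top, dna.N).astype(np.uint8)
        quals = np.where(ok, qual_sup, 0).astype(np.int16)
        for row, i in enumerate(idxs):
            chrom, start, umi, is_rev = families[i].key
            out[i] = ConsensusRead(chrom, start, bases[row], quals[row],
                                   size, umi, is_rev)
    return out  # type: ignore[return-value]


def filter_min_family(
    consensus: Iterable[ConsensusRead], min_size: int = 2
) -> list[ConsensusRead]:
    """Keep consensus reads backed by at least ``min_size`` PCR copies."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [c for c in consensus if c.family_size >= min_size]


def consensus_pipeline(
    reads: Iterable[AlignedRead],
    min_family_size: int = 2,
    concordance: float = DEFAULT_CONCORDANCE,
) -> list[ConsensusRead]:
    """Group, collapse and family-size-filter in one call."""
    return filter_min_family(
        collapse_families(group_families(reads), concordance), min_family_size
    )
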