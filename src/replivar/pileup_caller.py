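"""Per-position allele counting and matched-normal candidate calling.

Consensus reads (already family-size filtered) are piled up over the
target regions; N bases never contribute to depth, and overlapping mate
consensus reads from the same molecule are counted once.  Candidate
somatic SNVs are every position/alt with at least one nonreference
consensus allele in the case, tested against the matched white-blood-cell
(WBC) normal with a one-sided Fisher's exact test.  The default
thresholds are deliberately permissive — everything passes regardless of
counts and allele frequency — so that downstream replicate integration,
not the caller, does the error suppression.  A clonal-hematopoiesis
(CHIP) rule drops variants seen in the WBC normal unless the case VAF is
at least five-fold higher.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import fisher_exact

from . import dna
from .umi_consensus import ConsensusRead


class Reference:
    """Reference bases for the targeted regions, held as encoded arrays."""

    def __init__(self) -> None:
        self._seqs: dict[str, list[tuple[int, int, np.ndarray]]] = {}

    def add(self, chrom: str, start: int, seq: str | np.ndarray) -> "Reference":
        codes = dna.encode(seq) if isinstance(seq, str) else np.asarray(seq, np.uint8)
        self._seqs.setdefault(chrom, []).append((start, start + len(codes), codes))
        return self

    def base_at(self, chrom: str, pos: int) -> int:
        for start, end, codes in self._seqs.get(chrom, ()):
            if start <= pos < end:
                return int(codes[pos - start])
        raise KeyError(f"no reference base for {chrom}:{pos}")


@dataclass
class PositionPileup:
    """Allele counts from consensus reads at one 0-based position."""

    chrom: str
    pos: int
    ref: int  # base code
    counts: np.ndarray  # length-5 int array over A,C,G,T,N

    @property
    def depth(self) -> int:
        """Non-N consensus reads covering the position."""
        return int(self.counts[: dna.N].sum())


@dataclass
class CandidateVariant:
    """A case/normal-tested candidate somatic SNV."""

    chrom: str
    pos: int
    ref: int
    alt: int
    nra_count: int
    depth: int
    vaf: float
    fisher_p: float
    normal_nra: int
    normal_depth: int

    @property
    def key(self) -> tuple[str, int, int, int]:
        return (self.chrom, self.pos, self.ref, self.alt)


def merge_mate_overlaps(consensus: Sequence[ConsensusRead]) -> list[ConsensusRead]:
    """Collapse overlapping mate consensus reads of one molecule.

    Mates carry the same UMI but opposite orientations and are collapsed
    as separate families; where their footprints overlap, the overlap is
    counted once — agreeing bases are kept on one mate and blanked (N) on
    the other, disagreements are blanked on both.
    """
    by_umi: dict[tuple[str, str], list[ConsensusRead]] = {}
    out = []
    for c in consensus:
        cc = ConsensusRead(c.chrom, c.start, c.bases.copy(), c.quals.copy(),
                           c.family_size, c.umi, c.is_reverse)
        out.append(cc)
        if cc.umi:
            by_umi.setdefault((cc.chrom, cc.umi), []).append(cc)
    for reads in by_umi.values():
        if len(reads) < 2:
            continue
        for i, a in enumerate(reads):
            for b in reads[i + 1:]:
                if a.is_reverse == b.is_reverse:
                    continue
                lo = max(a.start, b.start)
                hi = min(a.end, b.end)
                if lo >= hi:
                    continue
                sa = slice(lo - a.start, hi - a.start)
                sb = slice(lo - b.start, hi - b.start)
                orig_a = a.bases[sa].copy()
                orig_b = b.bases[sb].copy()
                agree = orig_a == orig_b
                disagree = ~agree & (orig_a != dna.N) & (orig_b != dna.N)
                # count agreeing overlap once (on mate a); blank conflicts on both;
                # if one mate is already N the other stands
                a.bases[sa] = np.where(disagree, dna.N, orig_a)
                b.bases[sb] = np.where(agree | disagree, dna.N, orig_b)
    return out


def build_pileup(
    consensus: Iterable[ConsensusRead],
    targets,
    reference: Reference,
    dedup_mates: bool = True,
) -> list[PositionPileup]:
    """Pile consensus reads up over every target position.

    Returns one :class:`PositionPileup` per position of the (merged)
    target regions, in genomic order.  N consensus bases are tallied but
    excluded from depth.
    """
    from .io_formats import merge_regions

    regions = merge_regions(targets)
    reads = list(consensus)
    if dedup_mates:
        reads = merge_mate_overlaps(reads)

    pileups: list[PositionPileup] = []
    for reg in regions:
        counts = np.zeros((reg.width, 5), dtype=np.int64)
        flat = counts.reshape(-1)
        for c in reads:
            if c.chrom != reg.chrom:
                continue
            lo = max(c.start, reg.start)
            hi = min(c.end, reg.end)
            if lo >= hi:
                continue
            seg = c.bases[lo - c.start: hi - c.start].astype(np.int64)
            offs = (np.arange(lo, hi) - reg.start) * 5 + seg
            flat += np.bincount(offs, minlength=flat.size)
        for i in range(reg.width):
            pos = reg.start + i
            pileups.append(
                PositionPileup(
                    chrom=reg.chrom,
                    pos=pos,
                    ref=reference.base_at(reg.chrom, pos),
                    counts=counts[i],
                )
            )
    return pileups


def vaf_percent(nra_count: int, depth: int) -> float:
    """VAF as a percentage rounded half-even to 2 decimals (table style)."""
    if depth <= 0:
        raise ZeroDivisionError("VAF undefined at zero depth")
    if not 0 <= nra_count <= depth:
        raise ValueError("nra_count outside [0, depth]")
    frac = Decimal(100 * nra_count) / Decimal(depth)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def fisher_p_value(
    case_alt: int, case_ref: int, normal_alt: int, normal_ref: int,
    side: str = "greater",
) -> float:
    """One-sided (case-enriched) Fisher's exact p for a 2x2 allele table."""
    _, p = fisher_exact(
        [[case_alt, case_ref], [normal_alt, normal_ref]], alternative=side
    )
    return float(p)


def call_candidates(
    case: Sequence[PositionPileup],
    normal: Sequence[PositionPileup],
    max_p: float = 1.0,
    side: str = "greater",
) -> list[CandidateVariant]:
    """Emit every case position/alt with >=1 nonreference consensus allele.

    ``case`` and ``normal`` must cover the same positions.  Each alt
    allele at a multi-allelic position is an independent candidate.  The
    permissive default ``max_p`` = 1.0 disables the p filter, mirroring a
    caller configured to pass all SNVs.
    """
    if [(p.chrom, p.pos) for p in case] != [(p.chrom, p.pos) for p in normal]:
        raise ValueError("case and normal pileups cover different positions")
    out: list[CandidateVariant] = []
    for cp, np_ in zip(case, normal):
        depth = cp.depth
        if depth == 0:
            continue
        n_depth = np_.depth
        for alt in range(dna.N):
            if alt == cp.ref:
                continue
            a = int(cp.counts[alt])
            if a < 1:
                continue
            b = int(np_.counts[alt])
            p = fisher_p_value(a, depth - a, b, max(n_depth - b, 0), side=side)
            if p <= max_p:
                out.append(
                    CandidateVariant(
                        chrom=cp.chrom, pos=cp.pos, ref=cp.ref, alt=alt,
                        nra_count=a, depth=depth, vaf=a / depth,
                        fisher_p=p, normal_nra=b, normal_depth=n_depth,
                    )
                )
    return out


def chip_filter(
    candidate: CandidateVariant, fold: float = 5.0, strict: bool = False
) -> bool:
    """Clonal-hematopoiesis rule: True = keep.

    A variant also present in the WBC normal is kept only when the case
    VAF is ``fold``-fold (default five-fold, inclusive) higher than the
    normal VAF; ``strict`` switches the boundary to a strict >.
    """
    if candidate.normal_nra == 0:
        return True
    if candidate.normal_depth == 0:
        return True
    normal_vaf = candidate.normal_nra / candidate.normal_depth
    if strict:
        return candidate.vaf > fold * normal_vaf
    return candidate.vaf >= fold * normal_vaf


def apply_chip_filter(
    candidates: Iterable[CandidateVariant], fold: float = 5.0, strict: bool = False
) -> list[CandidateVariant]:
    return [c for c in candidates if chip_filter(c, fold=fold, strict=strict)]


def exon_filter(candidates: Iterable[CandidateVariant], exon_regions) -> list[CandidateVariant]:
    """Keep only candidates inside the exon regions (half-open)."""
    from .io_formats import region_lookup

    lookup = region_lookup(exon_regions)
    return [c for c in candidates if lookup.contains(c.chrom, c.pos)]
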