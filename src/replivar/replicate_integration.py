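"""Technical-replicate merging, threshold cascade, and tumor-informed search.

Two libraries prepared independently from the same ccfDNA extract see the
same true molecules but independent PCR/sequencing errors.  Requiring a
variant to appear in *both* replicates, each with more than three
nonreference consensus alleles, then restricting to known pathogenic
mutations of the target tissue, suppresses essentially all remaining
noise; the surviving variants define a patient's ctDNA status.

For merged variants the replicate counts are pooled to recombine the
allele fraction, and the shared Z-score is the geometric mean of the two
replicate Z-scores.

The tumor-informed mode inverts the logic: loci already known to be
mutated in the patient's tumor (present in both tumor replicates at a
combined VAF >= 1%) are interrogated in the pooled ccfDNA replicates
without requiring presence in both, with a combined nonreference count
of <= 3 scored as absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import dna
from .background_model import (
    BackgroundModel,
    ScoredVariant,
    score_candidates,
    threshold_z,
)
from .config import PipelineConfig
from .io_formats import AnnotationIndex, AnnotationRecord, to_vcf_pos
from .pileup_caller import (
    PositionPileup,
    Reference,
    apply_chip_filter,
    build_pileup,
    call_candidates,
    exon_filter,
)
from .umi_consensus import AlignedRead, consensus_pipeline


@dataclass
class SharedVariant:
    """A variant present in both technical replicates."""

    chrom: str
    pos: int
    ref: int
    alt: int
    nra1: int
    nra2: int
    depth1: int
    depth2: int
    z1: float
    z2: float
    annotation: Optional[AnnotationRecord] = None

    @property
    def combined_nra(self) -> int:
        return self.nra1 + self.nra2

    @property
    def combined_depth(self) -> int:
        return self.depth1 + self.depth2

    @property
    def combined_vaf(self) -> float:
        return self.combined_nra / self.combined_depth

    @property
    def shared_z(self) -> float:
        """Geometric mean of the replicate Z-scores; 0 unless both > 0."""
        if self.z1 > 0 and self.z2 > 0:
            return math.sqrt(self.z1 * self.z2)
        return 0.0

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TumorMutation:
    """A mutation catalogued from both tumor replicates (VAF >= 1%)."""

    chrom: str
    pos: int
    ref: int
    alt: int
    tumor_combined_vaf: float
    gene: str = ""

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TumorInformedResult:
    """A catalogued tumor locus interrogated in pooled ccfDNA replicates."""

    mutation: TumorMutation
    ccfdna_nra: int
    ccfdna_depth: int
    detected: bool
    covered: bool = True

    @property
    def ccfdna_vaf(self) -> float:
        return self.ccfdna_nra / self.ccfdna_depth if self.ccfdna_depth else 0.0


@dataclass
class DetectionResult:
    """Outcome of the full unbiased cascade for one patient sample."""

    variants: list[SharedVariant]
    detected: bool
    cascade: dict[str, int] = field(default_factory=dict)


def shared_variants(
    rep1: Sequence[ScoredVariant], rep2: Sequence[ScoredVariant]
) -> list[SharedVariant]:
    """Merge replicate calls, keeping only keys present in both."""
    by_key = {v.key: v for v in rep2}
    out = []
    for v1 in rep1:
        v2 = by_key.get(v1.key)
        if v2 is None:
            continue
        c1, c2 = v1.candidate, v2.candidate
        out.append(
            SharedVariant(
                chrom=c1.chrom, pos=c1.pos, ref=c1.ref, alt=c1.alt,
                nra1=c1.nra_count, nra2=c2.nra_count,
                depth1=c1.depth, depth2=c2.depth,
                z1=v1.z, z2=v2.z,
            )
        )
    return out


def nra_threshold(
    shared: Iterable[SharedVariant], min_nra_per_rep: int = 4
) -> list[SharedVariant]:
    """Require at least ``min_nra_per_rep`` nonreference alleles in *each*
    replicate (default 4, i.e. the published ">3 in each replicate")."""
    return [
        v for v in shared
        if v.nra1 >= min_nra_per_rep and v.nra2 >= min_nra_per_rep
    ]


def pathogenic_filter(
    shared: Iterable[SharedVariant],
    annotations: AnnotationIndex,
    tissue: str = "pancreas",
) -> list[SharedVariant]:
    """Keep only variants adjudicated pathogenic/likely-pathogenic for
    ``tissue``; retained variants carry their annotation record."""
    out = []
    for v in shared:
        rec = annotations.lookup(
            v.chrom, to_vcf_pos(v.pos), dna.BASES[v.ref], dna.BASES[v.alt]
        )
        if rec is not None and rec.is_pathogenic_for(tissue):
            v.annotation = rec
            out.append(v)
    return out


def _replicate_scored(
    reads: Iterable[AlignedRead],
    normal_pileup: Sequence[PositionPileup],
    model: BackgroundModel,
    targets,
    reference: Reference,
    cfg: PipelineConfig,
    cascade: dict[str, int],
    tag: str,
) -> list[ScoredVariant]:
    """One replicate through consensus -> pileup -> candidates -> filters."""
    consensus = consensus_pipeline(
        reads, min_family_size=cfg.min_family_size, concordance=cfg.concordance
    )
    pileup = build_pileup(consensus, targets, reference)
    candidates = call_candidates(pileup, normal_pileup, side=cfg.fisher_side)
    cascade[f"{tag}_candidates"] = len(candidates)
    candidates = apply_chip_filter(
        candidates, fold=cfg.chip_fold, strict=cfg.chip_strict
    )
    cascade[f"{tag}_after_chip"] = len(candidates)
    candidates = exon_filter(candidates, targets)
    cascade[f"{tag}_after_exon"] = len(candidates)
    scored = score_candidates(candidates, model, z_cap=cfg.z_cap)
    scored = threshold_z(scored, z_min=cfg.z_min)
    cascade[f"{tag}_after_z"] = len(scored)
    return scored


def detect_ctdna(
    rep1_reads: Iterable[AlignedRead],
    rep2_reads: Iterable[AlignedRead],
    normal_reads: Iterable[AlignedRead],
    model: BackgroundModel,
    annotations: AnnotationIndex,
    targets,
    reference: Reference,
    config: PipelineConfig | None = None,
) -> DetectionResult:
    """Run the full unbiased cascade for one patient sample.

    consensus -> pileup -> Fisher candidates vs the WBC normal -> CHIP and
    exon filters -> Z-score threshold -> shared-across-replicates ->
    per-replicate NRA threshold -> pathogenicity adjudication.  The
    patient is flagged detected when at least one variant survives.
    """
    cfg = config or PipelineConfig()
    cascade: dict[str, int] = {}
    normal_consensus = consensus_pipeline(
        normal_reads, min_family_size=cfg.min_family_size,
        concordance=cfg.concordance,
    )
    normal_pileup = build_pileup(normal_consensus, targets, reference)
    rep1 = _replicate_scored(
        rep1_reads, normal_pileup, model, targets, reference, cfg, cascade, "rep1")
    rep2 = _replicate_scored(
        rep2_reads, normal_pileup, model, targets, reference, cfg, cascade, "rep2")
    shared = shared_variants(rep1, rep2)
    cascade["shared"] = len(shared)
    shared = nra_threshold(shared, min_nra_per_rep=cfg.min_nra_per_rep)
    cascade["after_nra"] = len(shared)
    shared = pathogenic_filter(shared, annotations, tissue=cfg.tissue)
    cascade["after_pathogenic"] = len(shared)
    return DetectionResult(variants=shared, detected=len(shared) > 0,
                           cascade=cascade)


def catalog_tumor_mutations(
    tumor_rep1_reads: Iterable[AlignedRead],
    tumor_rep2_reads: Iterable[AlignedRead],
    normal_reads: Iterable[AlignedRead],
    targets,
    reference: Reference,
    min_vaf: float = 0.01,
    config: PipelineConfig | None = None,
    annotations: AnnotationIndex | None = None,
) -> list[TumorMutation]:
    """Catalogue somatic mutations from two tumor DNA replicates.

    A mutation qualifies when present in both tumor replicates with a
    combined (pooled-count) VAF of at least ``min_vaf`` and survives the
    CHIP rule against the WBC normal.
    """
    cfg = config or PipelineConfig()
    normal_pileup = build_pileup(
        consensus_pipeline(normal_reads, cfg.min_family_size, cfg.concordance),
        targets, reference)

    reps = []
    for reads in (tumor_rep1_reads, tumor_rep2_reads):
        pileup = build_pileup(
            consensus_pipeline(reads, cfg.min_family_size, cfg.concordance),
            targets, reference)
        candidates = call_candidates(pileup, normal_pileup, side=cfg.fisher_side)
        candidates = apply_chip_filter(
            candidates, fold=cfg.chip_fold, strict=cfg.chip_strict)
        reps.append({c.key: c for c in candidates})

    catalog = []
    for key, c1 in reps[0].items():
        c2 = reps[1].get(key)
        if c2 is None:
            continue
        combined_vaf = (c1.nra_count + c2.nra_count) / (c1.depth + c2.depth)
        if combined_vaf < min_vaf:
            continue
        gene = ""
        if annotations is not None:
            rec = annotations.lookup(
                c1.chrom, to_vcf_pos(c1.pos), dna.BASES[c1.ref], dna.BASES[c1.alt])
            if rec is not None:
                gene = rec.gene
        catalog.append(
            TumorMutation(chrom=c1.chrom, pos=c1.pos, ref=c1.ref, alt=c1.alt,
                          tumor_combined_vaf=combined_vaf, gene=gene)
        )
    return sorted(catalog, key=lambda m: (m.chrom, m.pos, m.alt))


def tumor_informed_search(
    catalog: Sequence[TumorMutation],
    ccf_rep1_pileup: Sequence[PositionPileup],
    ccf_rep2_pileup: Sequence[PositionPileup],
    absent_threshold: int = 3,
) -> list[TumorInformedResult]:
    """Interrogate catalogued tumor loci in pooled ccfDNA replicates.

    Replicate counts are pooled to maximize read-depth and presence in
    both replicates is *not* required; a combined nonreference count of
    <= ``absent_threshold`` is scored absent.  Loci the ccfDNA leaves
    uncovered are reported with zero depth and flagged.
    """
    by_pos1 = {(p.chrom, p.pos): p for p in ccf_rep1_pileup}
    by_pos2 = {(p.chrom, p.pos): p for p in ccf_rep2_pileup}
    results = []
    for mut in catalog:
        nra = 0
        depth = 0
        covered = False
        for lookup in (by_pos1, by_pos2):
            pp = lookup.get((mut.chrom, mut.pos))
            if pp is not None and pp.depth > 0:
                covered = True
                nra += int(pp.counts[mut.alt])
                depth += pp.depth
        results.append(
            TumorInformedResult(
                mutation=mut, ccfdna_nra=nra, ccfdna_depth=depth,
                detected=covered and nra > absent_threshold, covered=covered,
            )
        )
    return results
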