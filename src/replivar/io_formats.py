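"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based conventions of VCF and annotation tables happens only in this
module, at the format boundary.

Also hosts the packaged cohort fixtures: the 14-patient pancreatic
ductal adenocarcinoma (PDAC) cohort with survival follow-up, the
pre-/post-operative ccfDNA variant table, and a synthetic COSMIC-like
pathogenicity table used for adjudication.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
import pysam

from . import dna
from .umi_consensus import AlignedRead

log = logging.getLogger(__name__)

PATHOGENIC_CLASSES = frozenset({"pathogenic", "likely-pathogenic"})


@dataclass(frozen=True)
class TargetRegion:
    """A captured interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted region {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotationRecord:
    """One adjudicated variant from a COSMIC-like table (1-based ``pos``)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    cdna: str
    protein: str
    classification: str
    tissue: frozenset[str]

    def is_pathogenic_for(self, tissue: str) -> bool:
        return self.classification in PATHOGENIC_CLASSES and tissue in self.tissue


@dataclass(frozen=True)
class CohortRecord:
    """Per-patient follow-up used for survival stratification."""

    patient_id: str
    survival_days: int
    event: bool  # True = deceased
    preop_ctdna_detected: bool
    postop_day: Optional[int] = None


class AnnotationIndex:
    """Annotation records keyed genomically, with a gene+HGVS-c fallback.

    The genomic key is (chrom, pos [1-based], ref, alt); tables that lack
    coordinates for a variant are still reachable through (gene, cdna).
    Duplicate genomic keys are collapsed with a tissue-set union.
    """

    def __init__(self, records: Iterable[AnnotationRecord] = ()) -> None:
        self._by_locus: dict[tuple[str, int, str, str], AnnotationRecord] = {}
        self._by_hgvs: dict[tuple[str, str], AnnotationRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: AnnotationRecord) -> None:
        key = (rec.chrom, rec.pos, rec.ref, rec.alt)
        prev = self._by_locus.get(key)
        if prev is not None:
            rec = AnnotationRecord(
                prev.chrom, prev.pos, prev.ref, prev.alt, prev.gene,
                prev.cdna, prev.protein, prev.classification,
                prev.tissue | rec.tissue,
            )
        self._by_locus[key] = rec
        self._by_hgvs[(rec.gene, rec.cdna)] = rec

    def lookup(
        self,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        gene: str | None = None,
        cdna: str | None = None,
    ) -> Optional[AnnotationRecord]:
        rec = self._by_locus.get((chrom, pos, ref, alt))
        if rec is None and gene is not None and cdna is not None:
            rec = self._by_hgvs.get((gene, cdna))
        return rec

    def lookup_hgvs(self, gene: str, cdna: str) -> Optional[AnnotationRecord]:
        return self._by_hgvs.get((gene, cdna))

    def __len__(self) -> int:
        return len(self._by_locus)

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self._by_locus.values())


# ---------------------------------------------------------------------------
# coordinate conversion (the only place it happens)

def to_vcf_pos(pos0: int) -> int:
    """0-based internal position -> 1-based VCF/annotation position."""
    return pos0 + 1


def from_vcf_pos(pos1: int) -> int:
    """1-based VCF/annotation position -> 0-based internal position."""
    return pos1 - 1


# ---------------------------------------------------------------------------
# BED targets

def merge_regions(regions: Iterable[TargetRegion]) -> list[TargetRegion]:
    """Sort regions and merge overlapping or bookended ones (idempotent)."""
    merged: list[TargetRegion] = []
    for reg in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if merged and merged[-1].chrom == reg.chrom and reg.start <= merged[-1].end:
            prev = merged[-1]
            if reg.end > prev.end:
                merged[-1] = TargetRegion(prev.chrom, prev.start, reg.end, prev.label)
        else:
            merged.append(reg)
    return merged


def read_targets(path: str | Path) -> list[TargetRegion]:
    """Read a 3+ column BED (0-based half-open) into merged, sorted regions."""
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            label = fields[3] if len(fields) > 3 else ""
            regions.append(TargetRegion(chrom, start, end, label))
    return merge_regions(regions)


class _RegionLookup:
    """Per-chromosome sorted interval lookup over merged regions."""

    def __init__(self, regions: Iterable[TargetRegion]) -> None:
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for reg in merge_regions(regions):
            starts, ends = self._by_chrom.setdefault(reg.chrom, ([], []))
            starts.append(reg.start)
            ends.append(reg.end)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect_right(starts, start)
        if i > 0 and ends[i - 1] > start:
            return True
        return i < len(starts) and starts[i] < end

    def contains(self, chrom: str, pos: int) -> bool:
        return self.overlaps(chrom, pos, pos + 1)


def region_lookup(regions: Iterable[TargetRegion]) -> _RegionLookup:
    return _RegionLookup(regions)


# ---------------------------------------------------------------------------
# alignments

def _unclipped_start(read: pysam.AlignedSegment) -> int:
    """Reference start minus any leading soft/hard clip."""
    start = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (4, 5):  # soft, hard clip
            start -= length
        else:
            break
    return start


def read_alignments(
    path: str | Path,
    targets: Iterable[TargetRegion],
    umi_tag: str = "RX",
    umi_from_name: bool = False,
    skipped: dict | None = None,
) -> Iterator[AlignedRead]:
    """Stream on-target reads from a SAM/BAM file as :class:`AlignedRead`.

    The 8-mer UMI is taken from BAM tag ``umi_tag`` or, when
    ``umi_from_name`` is set, from the read-name suffix after the last
    colon.  Reads with a missing UMI or any non-ACGT character in the UMI
    are skipped and counted in ``skipped`` (key ``"bad_umi"``) when a dict
    is supplied; exact-match family grouping is undefined for ambiguous
    UMIs.
    """
    lookup = _RegionLookup(targets)
    n_bad = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not lookup.overlaps(
                read.reference_name, read.reference_start, read.reference_end
            ):
                continue
            if umi_from_name:
                umi = read.query_name.rsplit(":", 1)[-1]
            else:
                umi = read.get_tag(umi_tag) if read.has_tag(umi_tag) else None
            if umi is None or not dna.is_acgt(umi):
                n_bad += 1
                continue
            quals = read.query_qualities
            yield AlignedRead(
                chrom=read.reference_name,
                unclipped_start=_unclipped_start(read),
                umi=umi,
                bases=dna.encode(read.query_sequence),
                quals=np.asarray(quals, dtype=np.int16)
                if quals is not None
                else np.zeros(read.query_length, dtype=np.int16),
                is_reverse=read.is_reverse,
            )
    if n_bad:
        log.info("skipped %d reads with missing/ambiguous UMI", n_bad)
    if skipped is not None:
        skipped["bad_umi"] = skipped.get("bad_umi", 0) + n_bad


def _sam_header(contig_lengths: dict[str, int]) -> dict:
    return {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in contig_lengths.items()],
    }


def write_reads_sam(
    reads: Iterable[AlignedRead],
    path: str | Path,
    contig_lengths: dict[str, int],
    umi_tag: str = "RX",
) -> None:
    """Write aligned reads to a SAM file, UMI in both ``umi_tag`` and the
    read-name suffix (after the last colon), so either UMI-location
    convention reads them back."""
    header = _sam_header(contig_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, read in enumerate(reads):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = f"r{i}:{read.umi}"
            seg.reference_name = read.chrom
            seg.reference_start = read.unclipped_start
            seg.query_sequence = dna.decode(read.bases)
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(int(q), 60) + 33) for q in read.quals))
            seg.cigarstring = f"{len(read.bases)}M"
            seg.mapping_quality = 60
            seg.flag = 16 if read.is_reverse else 0
            seg.set_tag(umi_tag, read.umi)
            out.write(seg)


def write_consensus_sam(
    consensus,
    path: str | Path,
    contig_lengths: dict[str, int],
    umi_tag: str = "RX",
) -> None:
    """Write consensus reads to SAM; family size goes in the ``FS`` tag."""
    header = _sam_header(contig_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, c in enumerate(consensus):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = f"c{i}:{c.umi}" if c.umi else f"c{i}"
            seg.reference_name = c.chrom
            seg.reference_start = c.start
            seg.query_sequence = dna.decode(c.bases)
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(int(q), 60) + 33) for q in c.quals))
            seg.cigarstring = f"{len(c.bases)}M"
            seg.mapping_quality = 60
            seg.flag = 16 if c.is_reverse else 0
            if c.umi:
                seg.set_tag(umi_tag, c.umi)
            seg.set_tag("FS", int(c.family_size))
            out.write(seg)


def contig_lengths_for(targets: Iterable[TargetRegion], margin: int = 500) -> dict[str, int]:
    """Contig lengths big enough to hold the targets (for SAM headers)."""
    lengths: dict[str, int] = {}
    for t in targets:
        lengths[t.chrom] = max(lengths.get(t.chrom, 0), t.end + margin)
    return lengths


# ---------------------------------------------------------------------------
# annotation table

_REQUIRED_ANN_COLS = [
    "chrom", "pos", "ref", "alt", "gene", "cdna",
    "protein", "classification", "tissue",
]


def read_annotation_table(path: str | Path) -> AnnotationIndex:
    """Load a tab-delimited COSMIC-like table into an :class:`AnnotationIndex`.

    ``tissue`` may hold several tissues separated by ``;`` or ``,``;
    duplicate (chrom,pos,ref,alt) rows are collapsed with a tissue union.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _REQUIRED_ANN_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    index = AnnotationIndex()
    for row in df.itertuples(index=False):
        ref, alt = row.ref.upper(), row.alt.upper()
        if ref == alt:
            raise ValueError(f"{path}: ref == alt at {row.chrom}:{row.pos}")
        tissues = frozenset(
            t.strip().lower()
            for t in str(row.tissue).replace(";", ",").split(",")
            if t.strip()
        )
        if not tissues:
            raise ValueError(f"{path}: empty tissue at {row.chrom}:{row.pos}")
        index.add(
            AnnotationRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=ref,
                alt=alt,
                gene=str(row.gene),
                cdna=str(row.cdna),
                protein=str(row.protein),
                classification=str(row.classification).strip().lower(),
                tissue=tissues,
            )
        )
    return index


# ---------------------------------------------------------------------------
# VCF output

def write_vcf(variants, path: str | Path, reference_name: str = "unknown") -> None:
    """Write shared variants to an uncompressed VCF (v4.2; 1-based POS).

    INFO fields: NRA (combined nonreference count), DP (combined depth),
    VAF (combined allele fraction), Z (shared Z-score), SHARED flag and
    ANN (gene|cdna|protein) when an annotation is attached.  Unsorted
    input is sorted before writing (logged).
    """
    variants = list(variants)
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt))
    if ordered != variants:
        log.info("write_vcf: input not position-sorted; sorting")
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    header.add_line(f'##reference={reference_name}')
    header.add_line('##INFO=<ID=NRA,Number=1,Type=Integer,Description="Combined nonreference allele count">')
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined consensus read depth">')
    header.add_line('##INFO=<ID=VAF,Number=1,Type=Float,Description="Combined variant allele fraction">')
    header.add_line('##INFO=<ID=Z,Number=1,Type=Float,Description="Shared Z-score (geometric mean of replicates)">')
    header.add_line('##INFO=<ID=SHARED,Number=0,Type=Flag,Description="Present in both technical replicates">')
    header.add_line('##INFO=<ID=ANN,Number=1,Type=String,Description="gene|cdna|protein">')
    for chrom in dict.fromkeys(v.chrom for v in ordered):
        header.contigs.add(chrom)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in ordered:
            rec = vcf.new_record(
                contig=v.chrom,
                start=v.pos,  # pysam start is 0-based; POS printed 1-based
                alleles=(dna.BASES[v.ref] if isinstance(v.ref, (int, np.integer)) else v.ref,
                         dna.BASES[v.alt] if isinstance(v.alt, (int, np.integer)) else v.alt),
            )
            rec.info["NRA"] = int(v.combined_nra)
            rec.info["DP"] = int(v.combined_depth)
            rec.info["VAF"] = float(v.combined_vaf)
            rec.info["Z"] = float(v.shared_z)
            rec.info["SHARED"] = True
            ann = getattr(v, "annotation", None)
            if ann is not None:
                rec.info["ANN"] = f"{ann.gene}|{ann.cdna}|{ann.protein}"
            vcf.write(rec)


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read back a VCF written by :func:`write_vcf` (0-based ``pos``)."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.start,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "nra": rec.info["NRA"],
                    "depth": rec.info["DP"],
                    "vaf": float(rec.info["VAF"]),
                    "z": float(rec.info["Z"]),
                    "ann": rec.info.get("ANN"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "nra", "depth", "vaf", "z", "ann"],
    )


# ---------------------------------------------------------------------------
# packaged cohort fixtures

def _data_path(name: str):
    return resources.files("replivar.data").joinpath(name)


def load_variant_fixture() -> pd.DataFrame:
    """The packaged pre-/post-operative ccfDNA pathogenic-variant table.

    One row per variant per patient, with nonreference allele (NRA)
    counts, consensus read-depths, VAF (%) and Z-scores for the
    pre-operative sample and, where the mutation persisted, the
    post-operative sample (blank = mutation not detected post-op).
    """
    with resources.as_file(_data_path("ccfdna_variants.csv")) as p:
        return pd.read_csv(p)


def load_cohort_fixture() -> list[CohortRecord]:
    """The packaged 14-patient PDAC cohort with per-patient follow-up.

    ``preop_ctdna_detected`` is derived by joining against the packaged
    variant table (patients with at least one pre-operative pathogenic
    variant shared across replicates).
    """
    detected = set(load_variant_fixture()["patient_id"])
    with resources.as_file(_data_path("cohort_table.csv")) as p:
        df = pd.read_csv(p)
    records = []
    for row in df.itertuples(index=False):
        postop = None if pd.isna(row.postop_day) else int(row.postop_day)
        records.append(
            CohortRecord(
                patient_id=row.patient_id,
                survival_days=int(row.survival_days),
                event=(row.status == "Deceased"),
                preop_ctdna_detected=row.patient_id in detected,
                postop_day=postop,
            )
        )
    return records


def load_annotation_fixture() -> AnnotationIndex:
    """The packaged synthetic COSMIC-like pathogenicity table."""
    with resources.as_file(_data_path("synthetic_pathogenic_annotations.tsv")) as p:
        return read_annotation_table(p)
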