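"""End-to-end unbiased detection over a set of patient samples.

Drives :func:`replivar.replicate_integration.detect_ctdna` from files on
disk: per patient two ccfDNA replicate SAM/BAMs and a WBC normal, plus a
target BED, an annotation table, a fitted background model and a
reference.  Emits one VCF of surviving shared variants per patient plus
a detection-summary table, and logs the stage-by-stage variant counts
(the error-suppression cascade) so every drop is attributable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .background_model import BackgroundModel
from .config import PipelineConfig
from .io_formats import (
    AnnotationIndex,
    read_alignments,
    read_annotation_table,
    read_targets,
    write_vcf,
)
from .pileup_caller import Reference
from .replicate_integration import DetectionResult, detect_ctdna

log = logging.getLogger(__name__)


@dataclass
class SampleInputs:
    """File paths for one patient sample (two replicates + WBC normal)."""

    sample_id: str
    rep1: str
    rep2: str
    normal: str


def reference_from_fasta(path: str | Path, targets) -> Reference:
    """Load the target regions' reference bases from an indexed FASTA."""
    import pysam

    ref = Reference()
    with pysam.FastaFile(str(path)) as fa:
        for t in targets:
            ref.add(t.chrom, t.start, fa.fetch(t.chrom, t.start, t.end))
    return ref


def run_unbiased(
    samples: list[SampleInputs],
    bed_path: str | Path,
    annotation_path: str | Path,
    model: BackgroundModel,
    reference: Reference,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    umi_tag: str = "RX",
    umi_from_name: bool = False,
) -> pd.DataFrame:
    """Run the full cascade for every sample; returns the summary table.

    Writes ``<sample>.vcf`` per sample plus ``detection_summary.tsv`` and
    ``cascade.tsv`` under ``out_dir``.  Deterministic given fixed inputs.
    """
    cfg = config or PipelineConfig()
    targets = read_targets(bed_path)
    annotations = read_annotation_table(annotation_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summary_rows = []
    cascade_rows = []
    for sample in samples:
        def reads(path):
            return read_alignments(
                path, targets, umi_tag=umi_tag, umi_from_name=umi_from_name)

        result: DetectionResult = detect_ctdna(
            reads(sample.rep1), reads(sample.rep2), reads(sample.normal),
            model, annotations, targets, reference, config=cfg,
        )
        write_vcf(result.variants, out_dir / f"{sample.sample_id}.vcf")
        summary_rows.append(
            {
                "sample_id": sample.sample_id,
                "detected": result.detected,
                "n_variants": len(result.variants),
            }
        )
        cascade_rows.append({"sample_id": sample.sample_id, **result.cascade})
        log.info("%s: detected=%s variants=%d cascade=%s",
                 sample.sample_id, result.detected, len(result.variants),
                 result.cascade)

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out_dir / "detection_summary.tsv", sep="\t", index=False)
    pd.DataFrame(cascade_rows).to_csv(
        out_dir / "cascade.tsv", sep="\t", index=False)
    return summary
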