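"""Recompute the packaged cohort's headline numbers from its fixtures.

Everything here is derived at run time from the packaged Table-style
fixtures: per-variant VAF percentages are recomputed from the printed
nonreference allele counts and read-depths, the pre-operative detection
fraction from the variant table join, the persistent post-operative
variant count from the post-op columns, and the Kaplan-Meier medians and
Mantel-Cox chi-square from the survival records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import load_cohort_fixture, load_variant_fixture
from .pileup_caller import vaf_percent
from .survival import SurvivalReport, stratify_and_test


@dataclass
class CohortReport:
    n_patients: int
    n_detected: int
    detection_fraction_pct: float
    n_preop_variants: int
    n_persistent_postop_variants: int
    vaf_table: pd.DataFrame
    survival: SurvivalReport
    tumor_informed_survival: SurvivalReport | None = None


def reproduce_cohort(
    tumor_informed_flags: dict[str, bool] | None = None,
) -> CohortReport:
    """Rebuild the cohort analysis from the packaged fixtures.

    Optionally also runs a tumor-informed stratification when
    per-patient flags from that mode are supplied (the packaged fixtures
    carry unbiased-mode detection only).
    """
    cohort = load_cohort_fixture()
    variants = load_variant_fixture()

    vaf_rows = []
    for row in variants.itertuples(index=False):
        recomputed = vaf_percent(int(row.preop_nra), int(row.preop_depth))
        vaf_rows.append(
            {
                "patient_id": row.patient_id,
                "gene": row.gene,
                "cdna": row.cdna,
                "protein": row.protein,
                "nra": int(row.preop_nra),
                "depth": int(row.preop_depth),
                "vaf_pct": recomputed,
                "vaf_pct_table": float(row.preop_vaf_pct),
                "z": float(row.preop_z),
                "matches_table": recomputed == float(row.preop_vaf_pct),
            }
        )
    vaf_table = pd.DataFrame(vaf_rows)

    detected = sorted(set(variants["patient_id"]))
    persistent = int(variants["postop_nra"].notna().sum())

    report = stratify_and_test(cohort)
    tumor_report = None
    if tumor_informed_flags is not None:
        tumor_report = stratify_and_test(cohort, tumor_informed_flags)

    return CohortReport(
        n_patients=len(cohort),
        n_detected=len(detected),
        detection_fraction_pct=round(100.0 * len(detected) / len(cohort), 1),
        n_preop_variants=len(variants),
        n_persistent_postop_variants=persistent,
        vaf_table=vaf_table,
        survival=report,
        tumor_informed_survival=tumor_report,
    )


def format_report(report: CohortReport) -> str:
    s = report.survival
    lines = [
        f"patients: {report.n_patients}",
        f"pre-operative ctDNA detected: {report.n_detected} "
        f"({report.detection_fraction_pct}%)",
        f"pre-operative pathogenic variants: {report.n_preop_variants}",
        f"persistent post-operative variants: "
        f"{report.n_persistent_postop_variants}",
        f"KM median survival (ctDNA+): {s.median_positive:.0f} days",
        f"KM median survival (ctDNA-): {s.median_negative:.0f} days",
        f"log-rank chi2: {s.chi2:.1f}  (p = {s.p_value:.3f})",
        "",
        "recomputed VAFs vs fixture table:",
        report.vaf_table[
            ["patient_id", "gene", "cdna", "nra", "depth",
             "vaf_pct", "vaf_pct_table", "matches_table"]
        ].to_string(index=False),
    ]
    return "\n".join(lines)
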