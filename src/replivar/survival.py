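"""Kaplan-Meier estimation and Mantel-Cox log-rank comparison.

Stratifies patients by ctDNA detection status and asks whether the two
survival experiences differ.  Estimation and testing are delegated to
lifelines; this module fixes the conventions used throughout the
package: the median is the smallest observed event time at which the
product-limit estimate falls to 0.5 or below (undefined when never
reached), events precede censorings tied at the same day, and no
continuity correction is applied to the log-rank statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io_formats import CohortRecord


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: days, vital status, stratification group."""

    patient_id: str
    time: int
    event: bool  # True = deceased at `time`; False = censored
    group: str = ""

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")


@dataclass
class KmCurve:
    """A product-limit survival curve evaluated at the distinct times."""

    times: list[float]
    survival: list[float]
    n_risk: list[int]
    median: Optional[float]


def km_curve(records: Sequence[SurvivalRecord]) -> KmCurve:
    """Product-limit estimator; censored times shrink the risk set
    without a step.  ``median`` is the smallest event time with
    S(t) <= 0.5, or None when the curve never reaches 0.5."""
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter().fit(times, events)
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out_t, out_s, out_r = [], [], []
    for t in tab.index:
        if t == 0 and tab.loc[t, "observed"] == 0:
            continue
        out_t.append(float(t))
        out_s.append(float(surv.loc[t]))
        out_r.append(int(tab.loc[t, "at_risk"]))
    median = float(kmf.median_survival_time_)
    return KmCurve(
        times=out_t, survival=out_s, n_risk=out_r,
        median=None if math.isinf(median) else median,
    )


def logrank(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Mantel-Cox log-rank test (1 df): returns (chi2, p).

    Observed-minus-expected deaths accumulated over the distinct event
    times with the hypergeometric variance; no continuity correction.
    Degenerate inputs with no events at all return (0.0, 1.0).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in group_a) and not any(r.event for r in group_b):
        return 0.0, 1.0
    res = _ll_logrank(
        [r.time for r in group_a], [r.time for r in group_b],
        [r.event for r in group_a], [r.event for r in group_b],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalReport:
    """Medians, test statistics and step tables for one stratification."""

    n_positive: int
    n_negative: int
    median_positive: Optional[float]
    median_negative: Optional[float]
    chi2: Optional[float]
    p_value: Optional[float]
    curve_positive: Optional[KmCurve]
    curve_negative: Optional[KmCurve]
    warnings: list[str] = field(default_factory=list)


def stratify_and_test(
    cohort: Sequence[CohortRecord],
    detection_flags: dict[str, bool] | None = None,
) -> SurvivalReport:
    """Stratify a cohort into ctDNA-positive/negative and compare survival.

    ``detection_flags`` maps patient_id -> detected; when omitted the
    cohort records' own ``preop_ctdna_detected`` flags are used (e.g. to
    run a tumor-informed stratification, supply the flags from that
    mode).  If every patient lands in one group the log-rank test is
    undefined and the report says so instead of testing.
    """
    flags = detection_flags or {r.patient_id: r.preop_ctdna_detected for r in cohort}
    missing = [r.patient_id for r in cohort if r.patient_id not in flags]
    if missing:
        raise ValueError(f"detection flags missing for {missing}")
    pos = [
        SurvivalRecord(r.patient_id, r.survival_days, r.event, "positive")
        for r in cohort if flags[r.patient_id]
    ]
    neg = [
        SurvivalRecord(r.patient_id, r.survival_days, r.event, "negative")
        for r in cohort if not flags[r.patient_id]
    ]
    warnings: list[str] = []
    curve_p = km_curve(pos) if pos else None
    curve_n = km_curve(neg) if neg else None
    if not pos or not neg:
        warnings.append(
            "all patients fall in one group; log-rank test undefined")
        chi2 = p = None
    else:
        chi2, p = logrank(pos, neg)
    return SurvivalReport(
        n_positive=len(pos), n_negative=len(neg),
        median_positive=curve_p.median if curve_p else None,
        median_negative=curve_n.median if curve_n else None,
        chi2=chi2, p_value=p,
        curve_positive=curve_p, curve_negative=curve_n,
        warnings=warnings,
    )
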