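"""Position-specific background error model from a panel of normals.

Sequencing and PCR error is not uniform across a capture panel: some
positions carry systematic, patterned error.  A panel of healthy-control
ccfDNA samples — processed with the identical consensus and family-size
settings as the cases — supplies, for every (position, alt allele), the
mean and sample standard deviation of the background variant allele
frequency.  A candidate's Z-score is the number of panel standard
deviations its VAF sits above that mean.

Two practical guards keep the score finite and meaningful:

* ``sd_floor`` — at positions where the panel shows no error at all the
  standard deviation is zero; the floor defaults to 1/(median panel
  depth at the position), i.e. roughly the VAF quantum of a single
  chance nonreference allele, so zero-error positions still yield a very
  large (not infinite) score.
* ``z_cap`` — scores are capped at 100.0, the ceiling reported for
  variants at error-free positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import dna
from .pileup_caller import CandidateVariant, PositionPileup

#: default minimum Z retained by :func:`threshold_z`; the standard-normal
#: two-sided 99% critical value.
DEFAULT_Z_MIN = 2.576
DEFAULT_Z_CAP = 100.0


@dataclass
class _Entry:
    mean_af: float
    sd_af: float
    n_panel: int
    panel_depths: list[int]

    @property
    def median_depth(self) -> float:
        return float(np.median(self.panel_depths)) if self.panel_depths else 0.0


@dataclass
class ScoredVariant:
    """A candidate with its background Z-score attached."""

    candidate: CandidateVariant
    z: float

    @property
    def key(self):
        return self.candidate.key


@dataclass
class BackgroundModel:
    """Per-(chrom, pos, alt) background VAF statistics from the panel."""

    entries: dict[tuple[str, int, int], _Entry] = field(default_factory=dict)
    uncovered: set[tuple[str, int]] = field(default_factory=set)

    def entry(self, chrom: str, pos: int, alt: int) -> _Entry | None:
        return self.entries.get((chrom, pos, alt))

    def sd_floor(self, chrom: str, pos: int, alt: int) -> float:
        """1 / median panel depth — the single-allele VAF quantum."""
        e = self.entry(chrom, pos, alt)
        if e is None or e.median_depth <= 0:
            return 1.0  # uncovered: any VAF is within one 'floor' unit
        return 1.0 / e.median_depth

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "pos": p, "alt": dna.BASES[a], "mean_af": e.mean_af,
             "sd_af": e.sd_af, "n_panel": e.n_panel,
             "median_depth": e.median_depth}
            for (c, p, a), e in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "alt", "mean_af", "sd_af",
                           "n_panel", "median_depth"])

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "BackgroundModel":
        df = pd.read_csv(path, sep="\t")
        model = cls()
        for row in df.itertuples(index=False):
            md = float(row.median_depth)
            model.entries[(row.chrom, int(row.pos), dna.BASES.index(row.alt))] = _Entry(
                mean_af=float(row.mean_af), sd_af=float(row.sd_af),
                n_panel=int(row.n_panel),
                panel_depths=[int(round(md))] if md > 0 else [],
            )
        return model


def fit_background(panel: Sequence[Sequence[PositionPileup]]) -> BackgroundModel:
    """Fit per-position, per-alt background VAF statistics.

    Every panel sample contributes a VAF (zeros included) at each covered
    position; the model records the mean and the sample (n-1) standard
    deviation.  Positions a sample leaves uncovered (zero depth) are
    excluded from that position's statistics and flagged in
    ``model.uncovered``.  With a single covered sample the sd is 0 and
    scoring falls back to the floor.
    """
    if not panel:
        raise ValueError("empty panel")
    model = BackgroundModel()
    by_pos: dict[tuple[str, int], list[PositionPileup]] = {}
    for sample in panel:
        for pp in sample:
            by_pos.setdefault((pp.chrom, pp.pos), []).append(pp)
    for (chrom, pos), piles in by_pos.items():
        covered = [pp for pp in piles if pp.depth > 0]
        if len(covered) < len(panel):
            model.uncovered.add((chrom, pos))
        if not covered:
            continue
        depths = [pp.depth for pp in covered]
        ref = covered[0].ref
        for alt in range(dna.N):
            if alt == ref:
                continue
            vafs = np.array([pp.counts[alt] / pp.depth for pp in covered])
            sd = float(vafs.std(ddof=1)) if len(vafs) > 1 else 0.0
            model.entries[(chrom, pos, alt)] = _Entry(
                mean_af=float(vafs.mean()), sd_af=sd,
                n_panel=len(covered), panel_depths=depths,
            )
    return model


def zscore(
    candidate: CandidateVariant,
    model: BackgroundModel,
    z_cap: float = DEFAULT_Z_CAP,
) -> ScoredVariant:
    """Score one candidate against the background model.

    z = (vaf - mean_af) / max(sd_af, sd_floor), capped at ``z_cap``.  A
    position entirely free of panel error (mean and sd both zero) scores
    at the cap for any positive case VAF — a nonreference allele where
    the panel never errs is maximally surprising; the floor governs the
    remaining degenerate case of nonzero but spread-free panel error.
    """
    entry = model.entry(candidate.chrom, candidate.pos, candidate.alt)
    if entry is None:
        mean, sd = 0.0, 0.0
    else:
        mean, sd = entry.mean_af, entry.sd_af
    if mean == 0.0 and sd == 0.0:
        z = z_cap if candidate.vaf > 0 else 0.0
    else:
        floor = model.sd_floor(candidate.chrom, candidate.pos, candidate.alt)
        z = min((candidate.vaf - mean) / max(sd, floor), z_cap)
    return ScoredVariant(candidate=candidate, z=z)


def score_candidates(
    candidates: Iterable[CandidateVariant],
    model: BackgroundModel,
    z_cap: float = DEFAULT_Z_CAP,
) -> list[ScoredVariant]:
    return [zscore(c, model, z_cap=z_cap) for c in candidates]


def threshold_z(
    variants: Iterable[ScoredVariant], z_min: float = DEFAULT_Z_MIN
) -> list[ScoredVariant]:
    """Drop variants scoring below ``z_min`` (default 2.576)."""
    return [v for v in variants if v.z >= z_min]
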