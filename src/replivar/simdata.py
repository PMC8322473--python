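"""Synthetic ccfDNA sequencing data with full ground truth.

The generator emulates the statistical structure the pipeline assumes:

* unique input molecules (fragments), each tagged with a random 8-mer
  UMI and amplified into a PCR family (truncated-Poisson copy number);
* per-copy random sequencing/PCR error at a uniform per-base rate —
  suppressed by consensus collapsing;
* optional *early* PCR errors injected into every copy of a fragment —
  these survive consensus in one replicate but, being independent across
  replicates, are removed by the shared-variant rule;
* position-specific systematic error injected at the fragment level at a
  fixed per-site rate, shared across samples — what the panel-of-normals
  Z-score models;
* true variants ("spikes") assigned at the molecule level at a given
  VAF, so all PCR copies of a mutant molecule carry the variant — the
  property that lets UMI consensus preserve signal while erasing noise.

Every run returns a :class:`TruthManifest` recording exactly which
molecules carried what, so tests can compare pipeline output to truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from . import dna
from .io_formats import CohortRecord, TargetRegion
from .pileup_caller import PositionPileup, Reference, build_pileup
from .umi_consensus import AlignedRead, consensus_pipeline

AVOGADRO = 6.02214076e23
BP_WEIGHT_DA = 650.0
GENOME_BP = 3.3e9


@dataclass(frozen=True)
class Spike:
    """A true variant present in the extract at ``vaf`` (molecule level)."""

    pos: int  # 0-based genomic position
    ref: str
    alt: str
    vaf: float


@dataclass
class SimParams:
    """Conditions for one simulated technical replicate.

    Defaults model a targeted ccfDNA capture experiment: ~150 bp
    fragments, truncated-Poisson(3) PCR family sizes and a 0.5% per-base
    per-copy error rate (raw, pre-consensus).
    """

    target: TargetRegion
    n_fragments: int = 1000
    family_size_dist: tuple[str, float] = ("poisson", 3.0)
    per_base_error: float = 0.005
    systematic_error_sites: list[tuple[int, str, float]] = field(default_factory=list)
    spikes: list[Spike] = field(default_factory=list)
    read_length: int = 150
    early_pcr_error: float = 0.0
    base_quality: int = 37
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.per_base_error, self.early_pcr_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error rates must be probabilities")
        for spike in self.spikes:
            if not 0.0 <= spike.vaf <= 1.0:
                raise ValueError("spike VAF must be a fraction")
            if not self.target.start <= spike.pos < self.target.end:
                raise ValueError(
                    f"spike position {spike.pos} outside target "
                    f"{self.target.start}-{self.target.end}")
        name, _ = self.family_size_dist
        if name != "poisson":
            raise ValueError("only truncated-Poisson family sizes supported")


@dataclass
class TruthManifest:
    """Ground truth for one simulated replicate."""

    umis: list[str]
    starts: np.ndarray
    family_sizes: np.ndarray
    spike_molecules: dict[tuple[int, str], int]  # (pos, alt) -> molecule count
    n_reads: int
    true_bases: np.ndarray  # (n_fragments, fragment_length) codes


def make_reference(target: TargetRegion) -> Reference:
    """Deterministic synthetic reference for a target (seeded by locus)."""
    seed = zlib.crc32(f"{target.chrom}:{target.start}-{target.end}".encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=target.width).astype(np.uint8)
    return Reference().add(target.chrom, target.start, codes)


def _truncated_poisson(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    sizes = rng.poisson(lam, size=n)
    while True:
        zero = sizes == 0
        if not zero.any():
            return sizes
        sizes[zero] = rng.poisson(lam, size=int(zero.sum()))


def simulate_replicate(
    params: SimParams,
    rng: np.random.Generator | None = None,
    reference: Reference | None = None,
) -> tuple[list[AlignedRead], TruthManifest]:
    """Simulate one replicate's aligned reads plus its truth manifest.

    Fragments are placed at uniform starts inside the target (or cover
    the whole target when it is no wider than the read length); spikes
    and systematic errors are applied per molecule, per-copy errors per
    read.  A fixed seed reproduces the output exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    reference = reference if reference is not None else make_reference(params.target)
    target = params.target
    n = params.n_fragments
    frag_len = min(params.read_length, target.width)
    max_start = target.end - frag_len

    if max_start > target.start:
        starts = rng.integers(target.start, max_start + 1, size=n)
    else:
        starts = np.full(n, target.start, dtype=np.int64)

    ref_codes = np.array(
        [reference.base_at(target.chrom, p) for p in range(target.start, target.end)],
        dtype=np.uint8,
    )
    offsets = starts - target.start
    frag = ref_codes[offsets[:, None] + np.arange(frag_len)[None, :]].copy()

    spike_molecules: dict[tuple[int, str], int] = {}
    for spike in params.spikes:
        covers = (starts <= spike.pos) & (spike.pos < starts + frag_len)
        carrier = covers & (rng.random(n) < spike.vaf)
        frag[carrier, spike.pos - starts[carrier]] = dna.BASES.index(spike.alt)
        spike_molecules[(spike.pos, spike.alt)] = int(carrier.sum())

    for pos, alt, rate in params.systematic_error_sites:
        covers = (starts <= pos) & (pos < starts + frag_len)
        hit = covers & (rng.random(n) < rate)
        frag[hit, pos - starts[hit]] = dna.BASES.index(alt)

    if params.early_pcr_error > 0:
        early = rng.random((n, frag_len)) < params.early_pcr_error
        if early.any():
            shift = rng.integers(1, 4, size=int(early.sum())).astype(np.uint8)
            frag[early] = (frag[early] + shift) % 4

    lam = params.family_size_dist[1]
    sizes = _truncated_poisson(rng, lam, n)
    total_reads = int(sizes.sum())
    frag_idx = np.repeat(np.arange(n), sizes)
    reads_mat = frag[frag_idx]

    if params.per_base_error > 0:
        err = rng.random(reads_mat.shape) < params.per_base_error
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
            reads_mat = reads_mat.copy()
            reads_mat[err] = (reads_mat[err] + shift) % 4

    umi_codes = rng.integers(0, 4, size=(n, 8))
    umis = ["".join(dna.BASES[c] for c in row) for row in umi_codes]

    quals = np.full(frag_len, params.base_quality, dtype=np.int16)
    reads = [
        AlignedRead(
            chrom=target.chrom,
            unclipped_start=int(starts[i]),
            umi=umis[i],
            bases=reads_mat[j],
            quals=quals,
            is_reverse=False,
        )
        for j, i in enumerate(frag_idx)
    ]
    manifest = TruthManifest(
        umis=umis, starts=starts, family_sizes=sizes,
        spike_molecules=spike_molecules, n_reads=total_reads, true_bases=frag,
    )
    return reads, manifest


def simulate_replicate_pair(
    params: SimParams,
    shared_molecules: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[list[AlignedRead], TruthManifest],
           tuple[list[AlignedRead], TruthManifest]]:
    """Two technical replicates of the same extract.

    True variants share the underlying VAF but every molecule draw, PCR
    family and error realization is independent between replicates —
    each replicate is an independent library preparation.  With
    ``shared_molecules`` both replicates reuse replicate 1's molecule
    set (same spiked fragments), emulating splitting one library.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    reference = make_reference(params.target)
    rep1 = simulate_replicate(params, rng=rng, reference=reference)
    if shared_molecules:
        reads1, m1 = rep1
        params2 = replace(params, spikes=[], systematic_error_sites=[])
        # rebuild copies/errors over the same true molecules
        rep2 = _resample_copies(params2, m1, rng)
    else:
        rep2 = simulate_replicate(params, rng=rng, reference=reference)
    return rep1, rep2


def _resample_copies(
    params: SimParams, manifest: TruthManifest, rng: np.random.Generator
) -> tuple[list[AlignedRead], TruthManifest]:
    """New PCR families and per-copy errors over an existing molecule set."""
    frag = manifest.true_bases
    n, frag_len = frag.shape
    sizes = _truncated_poisson(rng, params.family_size_dist[1], n)
    frag_idx = np.repeat(np.arange(n), sizes)
    reads_mat = frag[frag_idx]
    if params.per_base_error > 0:
        err = rng.random(reads_mat.shape) < params.per_base_error
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
            reads_mat = reads_mat.copy()
            reads_mat[err] = (reads_mat[err] + shift) % 4
    umi_codes = rng.integers(0, 4, size=(n, 8))
    umis = ["".join(dna.BASES[c] for c in row) for row in umi_codes]
    quals = np.full(frag_len, params.base_quality, dtype=np.int16)
    reads = [
        AlignedRead(params.target.chrom, int(manifest.starts[i]), umis[i],
                    reads_mat[j], quals, False)
        for j, i in enumerate(frag_idx)
    ]
    return reads, TruthManifest(
        umis=umis, starts=manifest.starts, family_sizes=sizes,
        spike_molecules=dict(manifest.spike_molecules),
        n_reads=int(sizes.sum()), true_bases=frag,
    )


def simulate_panel(
    n_samples: int,
    params: SimParams,
    rng: np.random.Generator | None = None,
    min_family_size: int = 2,
    concordance: float = 0.66,
) -> list[list[PositionPileup]]:
    """A panel of independent error-only normal samples, as pileups.

    Spikes are stripped; systematic error sites are shared across all
    samples (they model patterned, reproducible error).  Each sample is
    consensus-collapsed and family-size filtered with the same settings
    as the cases before piling up, mirroring how a panel of normals must
    be processed.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    error_only = replace(params, spikes=[])
    reference = make_reference(params.target)
    panel = []
    for _ in range(n_samples):
        reads, _ = simulate_replicate(error_only, rng=rng, reference=reference)
        consensus = consensus_pipeline(reads, min_family_size, concordance)
        panel.append(build_pileup(consensus, [params.target], reference))
    return panel


def genomic_equivalents(mass_ng: float) -> float:
    """Haploid genome copies in ``mass_ng`` of human DNA.

    Uses 650 Da per base pair and a 3.3e9 bp genome: 10 ng of ccfDNA is
    ~2,800 genomic equivalents — the theoretical ceiling on unique
    consensus read-depth per 10 ng of library input.
    """
    if mass_ng < 0:
        raise ValueError("mass must be non-negative")
    grams = mass_ng * 1e-9
    moles = grams / (BP_WEIGHT_DA * GENOME_BP)
    return moles * AVOGADRO


def simulate_cohort(
    n_patients: int,
    detection_assignment: Sequence[bool],
    hazard_by_group: dict[bool, float],
    censoring_days: Optional[int] = None,
    censoring_prob: float = 0.0,
    seed: int = 0,
) -> list[CohortRecord]:
    """Synthetic survival cohort with exponential event times per group.

    ``hazard_by_group`` maps detection status to a per-day hazard.
    Administrative censoring truncates follow-up at ``censoring_days``;
    ``censoring_prob`` additionally censors a patient at a uniform
    fraction of their event time (independent random censoring).
    """
    if len(detection_assignment) != n_patients:
        raise ValueError("detection_assignment length != n_patients")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_patients):
        detected = bool(detection_assignment[i])
        hazard = hazard_by_group[detected]
        t = rng.exponential(1.0 / hazard)
        event = True
        if censoring_prob > 0 and rng.random() < censoring_prob:
            t = t * rng.random()
            event = False
        if censoring_days is not None and t > censoring_days:
            t = float(censoring_days)
            event = False
        records.append(
            CohortRecord(
                patient_id=f"S{i + 1}",
                survival_days=max(1, int(np.ceil(t))),
                event=event,
                preop_ctdna_detected=detected,
            )
        )
    return records
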