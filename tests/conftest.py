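"""Shared fixtures: a synthetic KRAS-like target, its reference, a fitted
panel-of-normals background model, and a pathogenic-site annotation."""

from __future__ import annotations

import numpy as np
import pytest

from replivar import dna
from replivar.background_model import fit_background
from replivar.io_formats import AnnotationIndex, AnnotationRecord, TargetRegion
from replivar.simdata import SimParams, make_reference, simulate_panel
from replivar.umi_consensus import AlignedRead

#: one 150 bp exon-sized window; reads span it fully, so consensus depth
#: is uniform across positions
SIM_TARGET = TargetRegion("chr12", 25398200, 25398350, "KRAS_exon2")
SPIKE_POS = 25398283  # a G in the synthetic reference; alt A below


@pytest.fixture(scope="session")
def sim_target() -> TargetRegion:
    return SIM_TARGET


@pytest.fixture(scope="session")
def sim_reference():
    return make_reference(SIM_TARGET)


@pytest.fixture(scope="session")
def spike_site(sim_reference):
    ref = dna.BASES[sim_reference.base_at(SIM_TARGET.chrom, SPIKE_POS)]
    alt = "A" if ref != "A" else "C"
    return SPIKE_POS, ref, alt


@pytest.fixture(scope="session")
def sim_annotations(spike_site) -> AnnotationIndex:
    pos, ref, alt = spike_site
    return AnnotationIndex(
        [
            AnnotationRecord(
                SIM_TARGET.chrom, pos + 1, ref, alt, "KRAS", "c.35G>A",
                "p.G12D", "pathogenic", frozenset({"pancreas"}),
            )
        ]
    )


@pytest.fixture(scope="session")
def panel_pileups():
    """Seven error-only normals at ~3,400x consensus depth."""
    params = SimParams(target=SIM_TARGET, n_fragments=4000,
                       per_base_error=0.005, seed=7)
    return simulate_panel(7, params)


@pytest.fixture(scope="session")
def background(panel_pileups):
    return fit_background(panel_pileups)


def mk_read(
    start: int,
    seq: str,
    umi: str = "ACGTACGT",
    chrom: str = "chr1",
    qual: int = 30,
    quals=None,
    is_reverse: bool = False,
) -> AlignedRead:
    """Terse AlignedRead constructor for hand-built examples."""
    q = (np.asarray(quals, dtype=np.int16) if quals is not None
         else np.full(len(seq), qual, dtype=np.int16))
    return AlignedRead(
        chrom=chrom, unclipped_start=start, umi=umi,
        bases=dna.encode(seq), quals=q, is_reverse=is_reverse,
    )
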