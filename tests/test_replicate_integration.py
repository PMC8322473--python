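"""Replicate merging, the threshold cascade, and the tumor-informed mode."""

from __future__ import annotations

import numpy as np
import pytest

from replivar import dna
from replivar.background_model import ScoredVariant
from replivar.config import PipelineConfig
from replivar.io_formats import AnnotationIndex, AnnotationRecord
from replivar.pileup_caller import CandidateVariant, PositionPileup, build_pileup
from replivar.replicate_integration import (
    SharedVariant,
    TumorMutation,
    catalog_tumor_mutations,
    detect_ctdna,
    nra_threshold,
    pathogenic_filter,
    shared_variants,
    tumor_informed_search,
)
from replivar.simdata import (
    SimParams,
    Spike,
    make_reference,
    simulate_replicate,
    simulate_replicate_pair,
)
from replivar.umi_consensus import consensus_pipeline


def _scored(pos, nra, depth, z, alt="G", chrom="chr1"):
    cand = CandidateVariant(chrom, pos, dna.A, dna.BASES.index(alt), nra,
                            depth, nra / depth, 0.5, 0, depth)
    return ScoredVariant(candidate=cand, z=z)


class TestSharedVariants:
    def test_variant_in_one_replicate_only_absent(self):
        rep1 = [_scored(5, 10, 1000, 8.0)]
        rep2 = [_scored(6, 10, 1000, 8.0)]
        assert shared_variants(rep1, rep2) == []

    def test_combined_arithmetic(self):
        (sv,) = shared_variants([_scored(5, 2, 1000, 4.0)],
                                [_scored(5, 3, 1000, 9.0)])
        assert sv.combined_nra == 5
        assert sv.combined_depth == 2000
        assert sv.combined_vaf == pytest.approx(0.0025)

    def test_geometric_mean_z(self):
        (sv,) = shared_variants([_scored(5, 4, 1000, 4.0)],
                                [_scored(5, 4, 1000, 9.0)])
        assert sv.shared_z == pytest.approx(6.0)

    def test_nonpositive_z_gives_zero_shared_z(self):
        (sv,) = shared_variants([_scored(5, 4, 1000, -1.0)],
                                [_scored(5, 4, 1000, 9.0)])
        assert sv.shared_z == 0.0

    def test_symmetric_under_replicate_swap(self):
        rep1 = [_scored(5, 4, 1000, 4.0), _scored(9, 6, 900, 3.0)]
        rep2 = [_scored(5, 7, 1100, 9.0)]
        fwd = shared_variants(rep1, rep2)
        rev = shared_variants(rep2, rep1)
        assert {v.key for v in fwd} == {v.key for v in rev}
        assert [v.shared_z for v in fwd] == [v.shared_z for v in rev]
        assert [v.combined_vaf for v in fwd] == [v.combined_vaf for v in rev]


class TestNraThreshold:
    def test_boundary_gt_three_in_each(self):
        keep = SharedVariant("chr1", 5, dna.A, dna.G, 4, 4, 100, 100, 5, 5)
        drop = SharedVariant("chr1", 6, dna.A, dna.G, 3, 10, 100, 100, 5, 5)
        assert nra_threshold([keep, drop]) == [keep]

    def test_min_one_keeps_all_shared(self):
        vs = [SharedVariant("chr1", 5, dna.A, dna.G, 1, 1, 100, 100, 5, 5)]
        assert nra_threshold(vs, min_nra_per_rep=1) == vs


class TestPathogenicFilter:
    ANN = AnnotationIndex(
        [
            AnnotationRecord("chr12", 25398284, "C", "T", "KRAS", "c.35G>A",
                             "p.G12D", "pathogenic", frozenset({"pancreas"})),
            AnnotationRecord("chr1", 100, "A", "G", "X", "c.1A>G", "p.M1V",
                             "pathogenic", frozenset({"lung"})),
        ]
    )

    def _sv(self, chrom, pos0, ref, alt):
        return SharedVariant(chrom, pos0, dna.BASES.index(ref),
                             dna.BASES.index(alt), 5, 5, 100, 100, 5, 5)

    def test_pancreas_pathogenic_retained_with_annotation(self):
        (kept,) = pathogenic_filter(
            [self._sv("chr12", 25398283, "C", "T")], self.ANN)
        assert kept.annotation.gene == "KRAS"

    def test_unannotated_variant_dropped(self):
        assert pathogenic_filter(
            [self._sv("chr12", 25398284, "C", "T")], self.ANN) == []

    def test_wrong_tissue_dropped(self):
        assert pathogenic_filter(
            [self._sv("chr1", 99, "A", "G")], self.ANN) == []


class TestDetectCtdna:
    def _normal(self, sim_target, seed):
        reads, _ = simulate_replicate(
            SimParams(target=sim_target, n_fragments=3000,
                      per_base_error=0.005, seed=seed))
        return reads

    def test_spike_detected_and_cascade_monotone(
        self, sim_target, sim_reference, sim_annotations, background, spike_site
    ):
        pos, ref, alt = spike_site
        params = SimParams(
            target=sim_target, n_fragments=11_900, per_base_error=0.005,
            spikes=[Spike(pos, ref, alt, 0.003)], seed=1234)
        (r1, _), (r2, _) = simulate_replicate_pair(
            params, rng=np.random.default_rng(1234))
        res = detect_ctdna(r1, r2, self._normal(sim_target, 555), background,
                           sim_annotations, [sim_target], sim_reference)
        assert res.detected
        (v,) = res.variants
        assert (v.pos, dna.BASES[v.alt]) == (pos, alt)
        assert v.nra1 > 3 and v.nra2 > 3
        c = res.cascade
        # each stage can only remove variants
        for tag in ("rep1", "rep2"):
            assert (c[f"{tag}_candidates"] >= c[f"{tag}_after_chip"]
                    >= c[f"{tag}_after_exon"] >= c[f"{tag}_after_z"])
        assert c["shared"] >= c["after_nra"] >= c["after_pathogenic"]

    def test_error_only_control_not_detected(
        self, sim_target, sim_reference, sim_annotations, background
    ):
        params = SimParams(target=sim_target, n_fragments=4500,
                           per_base_error=0.005, seed=77)
        (r1, _), (r2, _) = simulate_replicate_pair(
            params, rng=np.random.default_rng(77))
        res = detect_ctdna(r1, r2, self._normal(sim_target, 888), background,
                           sim_annotations, [sim_target], sim_reference)
        assert not res.detected
        assert res.variants == []

    def test_early_pcr_errors_survive_consensus_but_not_sharing(
        self, sim_target, sim_reference, sim_annotations, background
    ):
        """Errors struck in the first PCR cycle propagate to all copies
        of a fragment, so consensus keeps them — but they are private to
        one replicate and die at the shared-variant step."""
        params = SimParams(target=sim_target, n_fragments=4000,
                           per_base_error=0.0, early_pcr_error=0.001,
                           seed=202)
        (r1, _), (r2, _) = simulate_replicate_pair(
            params, rng=np.random.default_rng(202))
        cfg = PipelineConfig()
        normal = self._normal(sim_target, 999)
        res = detect_ctdna(r1, r2, normal, background, sim_annotations,
                          [sim_target], sim_reference, config=cfg)
        # plenty of per-replicate candidates from early PCR errors...
        assert res.cascade["rep1_candidates"] > 10
        assert res.cascade["rep2_candidates"] > 10
        # ...but essentially none recur at the same position/alt in both
        assert res.cascade["after_nra"] == 0
        assert not res.detected


class TestTumorInformed:
    def _pileups(self, reads, sim_target, sim_reference):
        return build_pileup(consensus_pipeline(reads), [sim_target],
                            sim_reference)

    def test_catalog_vaf_boundary(self, sim_target, sim_reference):
        def scored_pileups(vaf, seed):
            params = SimParams(
                target=sim_target, n_fragments=3000, per_base_error=0.0,
                spikes=[Spike(SPIKE[0], SPIKE[1], SPIKE[2], vaf)], seed=seed)
            return simulate_replicate_pair(
                params, rng=np.random.default_rng(seed))

        SPIKE = (sim_target.start + 50,
                 dna.BASES[sim_reference.base_at(sim_target.chrom,
                                                 sim_target.start + 50)],
                 "T")
        if SPIKE[1] == "T":
            SPIKE = (SPIKE[0], SPIKE[1], "C")
        (t1, _), (t2, _) = scored_pileups(0.20, 42)
        normal, _ = simulate_replicate(
            SimParams(target=sim_target, n_fragments=2000,
                      per_base_error=0.0, seed=9))
        catalog = catalog_tumor_mutations(
            t1, t2, normal, [sim_target], sim_reference)
        (mut,) = catalog
        assert (mut.pos, dna.BASES[mut.alt]) == (SPIKE[0], SPIKE[2])
        # combined VAF within binomial error of the 20% truth
        sigma = np.sqrt(0.2 * 0.8 / 5000)
        assert abs(mut.tumor_combined_vaf - 0.20) < 4 * sigma

    def test_catalog_min_vaf_excludes_low_fraction(self, sim_target, sim_reference):
        # hand-built pileup path: combined VAF 0.9% excluded, 1.0% kept
        def sv(vaf1, vaf2):
            out = []
            for vaf in (vaf1, vaf2):
                counts = np.zeros(5, dtype=np.int64)
                counts[dna.A] = 1000 - int(vaf * 1000)
                counts[dna.G] = int(vaf * 1000)
                out.append([PositionPileup("chr1", 5, dna.A, counts)])
            return out

        from replivar.pileup_caller import call_candidates
        normal = [PositionPileup("chr1", 5, dna.A,
                                 np.array([1000, 0, 0, 0, 0]))]
        low: dict = {}
        for vaf, expected in ((0.009, 0), (0.010, 1)):
            reps = sv(vaf, vaf)
            cands = [
                {c.key: c for c in call_candidates(rep, normal)}
                for rep in reps
            ]
            shared_keys = set(cands[0]) & set(cands[1])
            kept = []
            for key in shared_keys:
                c1, c2 = cands[0][key], cands[1][key]
                combined = (c1.nra_count + c2.nra_count) / (c1.depth + c2.depth)
                if combined >= 0.01:
                    kept.append(key)
            assert len(kept) == expected

    def test_absent_threshold_boundary(self):
        mut = TumorMutation("chr1", 5, dna.A, dna.G, 0.2)

        def pileup(nra):
            counts = np.zeros(5, dtype=np.int64)
            counts[dna.A] = 4000 - nra
            counts[dna.G] = nra
            return [PositionPileup("chr1", 5, dna.A, counts)]

        (absent,) = tumor_informed_search([mut], pileup(1), pileup(2))
        assert absent.ccfdna_nra == 3 and not absent.detected
        (found,) = tumor_informed_search([mut], pileup(2), pileup(2))
        assert found.ccfdna_nra == 4 and found.detected

    def test_empty_catalog(self):
        assert tumor_informed_search([], [], []) == []

    def test_uncovered_locus_flagged(self):
        mut = TumorMutation("chr1", 5, dna.A, dna.G, 0.2)
        (res,) = tumor_informed_search([mut], [], [])
        assert not res.covered and not res.detected and res.ccfdna_depth == 0

    def test_tumor_informed_detects_superset_at_catalogued_loci(
        self, sim_target, sim_reference, sim_annotations, background, spike_site
    ):
        """At a catalogued locus the relaxed tumor-informed rule
        (combined NRA > 3, no both-replicates requirement) detects
        whenever the unbiased cascade does."""
        pos, ref, alt = spike_site
        for seed, vaf in ((5, 0.0015), (6, 0.003), (7, 0.0008)):
            params = SimParams(
                target=sim_target, n_fragments=6000, per_base_error=0.005,
                spikes=[Spike(pos, ref, alt, vaf)], seed=seed)
            (r1, _), (r2, _) = simulate_replicate_pair(
                params, rng=np.random.default_rng(seed))
            normal, _ = simulate_replicate(
                SimParams(target=sim_target, n_fragments=3000,
                          per_base_error=0.005, seed=seed + 100))
            res = detect_ctdna(r1, r2, normal, background, sim_annotations,
                               [sim_target], sim_reference)
            mut = TumorMutation(sim_target.chrom, pos, dna.BASES.index(ref),
                                dna.BASES.index(alt), 0.2)
            (ti,) = tumor_informed_search(
                [mut],
                self._pileups(r1, sim_target, sim_reference),
                self._pileups(r2, sim_target, sim_reference),
            )
            if res.detected:
                assert ti.detected
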