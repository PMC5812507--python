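"""Breakpoint detection, dual-reference construction and spanning-read
classification."""

from collections import Counter

import numpy as np
import pytest

from nanocurate.io_formats import FeatureRecord, Genome, SequenceRecord, revcomp
from nanocurate.simulate import (SimConfig, apply_translocation,
                                 simulate_genome, simulate_reads)
from nanocurate.structvar import (ArchitectureSupport, build_dual_reference,
                                  BreakpointPair, call_heterogeneity,
                                  classify_spanning_reads, detect_breakpoints,
                                  find_flanking_unique_genes)
from conftest import random_seq


def _transloc_cfg(seed, mixture=0.2, coverage=25.0, **kw):
    base = dict(n_chromosomes=2, chromosome_length_range=(90_000, 130_000),
                n_repeat_elements=3, n_genes=25, translocation=(0, 1),
                mixture_fraction=mixture, read_coverage=coverage,
                read_length_mean=8_000, seed=seed)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="module")
def transloc_world():
    cfg = _transloc_cfg(seed=31)
    g, ann, truth = simulate_genome(cfg)
    g.name = "normal"
    var, truth = apply_translocation(g, truth)
    return cfg, g, ann, truth, var


class TestDetectBreakpoints:
    def test_identical_genomes_yield_no_events(self, transloc_world):
        _cfg, g, _ann, _truth, _var = transloc_world
        assert detect_breakpoints(g, g) == []

    def test_planted_translocation_recovered_within_repeat(self, transloc_world):
        _cfg, g, _ann, truth, var = transloc_world
        (event,) = detect_breakpoints(var, g)
        assert {event.chrA, event.chrB} == {truth.chrA, truth.chrB}
        pos = {event.chrA: event.posA, event.chrB: event.posB}
        assert truth.repeatA[0] <= pos[truth.chrA] <= truth.repeatA[1]
        assert truth.repeatB[0] <= pos[truth.chrB] <= truth.repeatB[1]

    def test_recovery_across_random_simulations(self):
        """Breakpoint error stays within the mediating repeat for several
        independently seeded translocations."""
        for seed in range(40, 46):
            cfg = _transloc_cfg(seed=seed)
            g, _ann, truth = simulate_genome(cfg)
            var, truth = apply_translocation(g, truth)
            (event,) = detect_breakpoints(var, g)
            pos = {event.chrA: event.posA, event.chrB: event.posB}
            assert truth.repeatA[0] <= pos[truth.chrA] <= truth.repeatA[1], seed
            assert truth.repeatB[0] <= pos[truth.chrB] <= truth.repeatB[1], seed

    def test_internal_inversion_is_not_a_translocation(self, rng):
        seq = random_seq(rng, 80_000)
        ref = Genome([(SequenceRecord("chr", seq), False)])
        inv = seq[:30_000] + revcomp(seq[30_000:50_000]) + seq[50_000:]
        asm = Genome([(SequenceRecord("ctg", inv), False)])
        assert detect_breakpoints(asm, ref) == []


class TestBuildDualReference:
    def test_lengths_and_originals_preserved(self, rng):
        a, b = random_seq(rng, 300_000), random_seq(rng, 500_000)
        ref = Genome([(SequenceRecord("chrA", a), False),
                      (SequenceRecord("chrB", b), False)], name="ref")
        bp = BreakpointPair("chrA", "chrB", 250_000, 70_000)
        dual = build_dual_reference(ref, bp)
        assert len(dual["chrA-chrB"]) == 250_000 + (500_000 - 70_000)
        assert len(dual["chrB-chrA"]) == 70_000 + (300_000 - 250_000)
        assert dual["chrA"].sequence == a and dual["chrB"].sequence == b
        assert dual.total_length() == ref.total_length() + 300_000 + 500_000

    def test_tile_conservation_away_from_junctions(self, rng):
        a, b = random_seq(rng, 60_000), random_seq(rng, 80_000)
        ref = Genome([(SequenceRecord("chrA", a), False),
                      (SequenceRecord("chrB", b), False)])
        bp = BreakpointPair("chrA", "chrB", 40_000, 30_000)
        dual = build_dual_reference(ref, bp)

        def tiles(seq):
            return Counter(seq[i:i + 1_000]
                           for i in range(0, len(seq) - 999, 1_000))

        orig = tiles(a) + tiles(b)
        new = tiles(dual["chrA-chrB"].sequence) \
            + tiles(dual["chrB-chrA"].sequence)
        diff = (orig - new) + (new - orig)
        assert sum(diff.values()) <= 4  # only junction-crossing tiles differ

    def test_out_of_bounds_breakpoint_rejected(self, rng):
        ref = Genome([(SequenceRecord("chrA", random_seq(rng, 10_000)), False),
                      (SequenceRecord("chrB", random_seq(rng, 10_000)), False)])
        with pytest.raises(ValueError, match="bounds"):
            build_dual_reference(ref, BreakpointPair("chrA", "chrB", 50_000, 5_000))


class TestFlankingGenes:
    def test_planted_flanks_recovered(self, transloc_world):
        _cfg, g, ann, truth, var = transloc_world
        (event,) = detect_breakpoints(var, g)
        bp = find_flanking_unique_genes(event, ann)
        got = {
            "A_left": bp.flankA_left.gene_name,
            "A_right": bp.flankA_right.gene_name,
            "B_left": bp.flankB_left.gene_name,
            "B_right": bp.flankB_right.gene_name,
        }
        assert got == truth.flank_genes

    def test_duplicated_name_skipped_for_next_unique(self):
        ann = [
            FeatureRecord("chrA", 1_000, 2_000, "+", "gene", "FARLEFT"),
            FeatureRecord("chrA", 5_000, 6_000, "+", "gene", "TWICE"),
            FeatureRecord("chrB", 1_000, 2_000, "+", "gene", "TWICE"),
            FeatureRecord("chrA", 12_000, 13_000, "+", "gene", "RIGHT1"),
            FeatureRecord("chrB", 7_000, 8_000, "+", "gene", "BLEFT"),
            FeatureRecord("chrB", 12_000, 13_000, "+", "gene", "BRIGHT"),
            FeatureRecord("chrA", 8_000, 10_000, "+", "dispersed_repeat", "Ty"),
            FeatureRecord("chrB", 9_000, 10_000, "+", "dispersed_repeat", "Ty"),
        ]
        bp = BreakpointPair("chrA", "chrB", 9_000, 9_500)
        out = find_flanking_unique_genes(bp, ann)
        assert out.flankA_left.gene_name == "FARLEFT"  # TWICE is ambiguous
        assert out.flankA_right.gene_name == "RIGHT1"

    def test_missing_flank_is_an_error(self):
        ann = [FeatureRecord("chrA", 12_000, 13_000, "+", "gene", "ONLYRIGHT"),
               FeatureRecord("chrB", 1_000, 2_000, "+", "gene", "BL"),
               FeatureRecord("chrB", 12_000, 13_000, "+", "gene", "BR")]
        bp = BreakpointPair("chrA", "chrB", 9_000, 9_500)
        with pytest.raises(ValueError, match="left of chrA"):
            find_flanking_unique_genes(bp, ann)


@pytest.fixture(scope="module")
def classified(transloc_world):
    cfg, g, ann, truth, var = transloc_world
    (event,) = detect_breakpoints(var, g)
    bp = find_flanking_unique_genes(event, ann)
    dual = build_dual_reference(g, bp)
    reads, origins = simulate_reads([(var, cfg.mixture_fraction),
                                     (g, 1 - cfg.mixture_fraction)], cfg)
    support = classify_spanning_reads(reads, dual, bp)
    return truth, origins, support


class TestSpanningReads:
    def test_no_supporter_contradicts_its_origin(self, classified):
        truth, origins, support = classified
        origin_of = {o.read_id: o.architecture for o in origins}
        for arch_name, ids in support.support.items():
            expected = ("translocated" if arch_name.startswith("transloc")
                        else "normal")
            assert all(origin_of[r] == expected for r in ids), arch_name

    def test_reads_assigned_at_most_once(self, classified):
        _truth, _origins, support = classified
        all_ids = [r for ids in support.support.values() for r in ids]
        assert len(all_ids) == len(set(all_ids))
        assert not set(all_ids) & set(support.ambiguous)

    def test_both_architectures_supported_in_mixture(self, classified):
        _truth, _origins, support = classified
        normal, trans = support.side_counts()
        assert normal >= 1 and trans >= 1


class TestCallHeterogeneity:
    def test_both_sides_supported_is_heterogeneous(self):
        sup = ArchitectureSupport(support={"transloc_AB": [f"r{i}" for i in range(8)],
                                           "normal_A": ["r8"]})
        call = call_heterogeneity(sup)
        assert call.verdict == "heterogeneous"
        assert (call.normal_reads, call.translocated_reads) == (1, 8)

    def test_one_side_only_is_single_architecture(self):
        sup = ArchitectureSupport(support={"normal_A": ["r0"], "transloc_AB": []})
        assert call_heterogeneity(sup).verdict == "single_architecture"

    def test_no_support_is_inconclusive(self):
        assert call_heterogeneity(ArchitectureSupport()).verdict == "inconclusive"

    def test_min_reads_threshold_applies_to_both_sides(self):
        sup = ArchitectureSupport(support={"normal_A": ["r0"],
                                           "transloc_AB": ["r1", "r2", "r3"]})
        assert call_heterogeneity(sup, min_reads=1).verdict == "heterogeneous"
        assert call_heterogeneity(sup, min_reads=2).verdict == "single_architecture"
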