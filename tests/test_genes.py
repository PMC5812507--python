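"""Gene-set comparison: name differences, unique-ORF classification,
repeat census and panel attribution."""

import numpy as np
import pytest

from nanocurate.genes import (census_repeat_family, classify_unique_orfs,
                              compare_gene_names, panel_attribution)
from nanocurate.io_formats import FeatureRecord, Genome, SequenceRecord, revcomp
from nanocurate.simulate import mutate_sequence
from conftest import random_seq


def _feat(seqid, name, i=0):
    return FeatureRecord(seqid, 1_000 + 200 * i, 2_500 + 200 * i, "+",
                         "gene", name)


class TestCompareGeneNames:
    def test_identical_annotations_give_empty_difference(self):
        ann = [_feat("chr1", "MAL31"), _feat("chr2", "FLO1", 1)]
        nc = compare_gene_names(ann, list(ann))
        assert nc.unique_to_a == [] and nc.unique_to_b == []

    def test_gene_only_in_one_genome_is_unique(self):
        a = [_feat("chr3", "MAL13"), _feat("chr1", "SHARED", 1)]
        b = [_feat("chr1", "SHARED", 1)]
        nc = compare_gene_names(a, b)
        assert [f.gene_name for f in nc.unique_to_a] == ["MAL13"]
        assert nc.unique_to_b == []

    def test_relocated_gene_flagged_on_both_sides(self):
        a = [_feat("chr1", "HXT17")]
        b = [_feat("chr9", "HXT17")]
        nc = compare_gene_names(a, b, per_chromosome=True)
        assert [f.gene_name for f in nc.unique_to_a] == ["HXT17"]
        assert [f.gene_name for f in nc.unique_to_b] == ["HXT17"]
        assert nc.relocated == ["HXT17"]
        # without per-chromosome resolution the name is shared
        nc2 = compare_gene_names(a, b, per_chromosome=False)
        assert nc2.unique_to_a == [] and nc2.unique_to_b == []

    def test_case_and_duplicate_markers_ignored_unnamed_counted(self):
        a = [_feat("chr1", "mal31"), _feat("chr1", "", 1)]
        b = [_feat("chr1", "MAL31_dup2")]
        nc = compare_gene_names(a, b)
        assert nc.unique_to_a == [] and nc.unique_to_b == []
        assert nc.n_unnamed_a == 1


@pytest.fixture
def planted_orf_scenario(rng):
    """Genome pair sharing 10 genes; A additionally carries 5 novel genes
    with no counterpart in B and 3 genes whose B copies diverged to 90%
    identity under different names."""
    shared = {f"SH{i}": random_seq(rng, 1_500) for i in range(10)}
    novel = {f"NOV{i}": random_seq(rng, 1_500) for i in range(5)}
    div = {f"DIV{i}": random_seq(rng, 1_500) for i in range(3)}
    orfs_a = {**shared, **novel, **div}
    orfs_b = {**shared,
              **{f"BD{i}": mutate_sequence(div[f"DIV{i}"], 0.10, rng)
                 for i in range(3)}}
    ann_a = [_feat("chr1", n, i) for i, n in enumerate(orfs_a)]
    ann_b = [_feat("chr1", n, i) for i, n in enumerate(orfs_b)]
    return ann_a, ann_b, orfs_a, orfs_b


class TestClassifyUniqueOrfs:
    def test_novel_vs_diverged_split(self, planted_orf_scenario):
        ann_a, ann_b, orfs_a, orfs_b = planted_orf_scenario
        nc = compare_gene_names(ann_a, ann_b)
        rep = classify_unique_orfs(nc.unique_to_a, orfs_a, orfs_b)
        assert sorted(rep.truly_absent) == [f"NOV{i}" for i in range(5)]
        assert sorted(rep.diverged_matches) == [f"DIV{i}" for i in range(3)]
        assert not set(rep.truly_absent) & set(rep.homologue_map)

    def test_high_identity_match_is_homologue(self, rng):
        seq = random_seq(rng, 1_500)
        near = mutate_sequence(seq, 0.02, rng)  # ~98% identity
        rep = classify_unique_orfs([_feat("chr1", "CAND")],
                                   {"CAND": seq}, {"OTHER": near})
        assert rep.truly_absent == []
        ((tid, ident, cov),) = rep.homologue_map["CAND"]
        assert tid == "OTHER" and ident >= 0.95 and cov >= 0.5

    def test_low_coverage_match_not_qualifying(self, rng):
        seq = random_seq(rng, 2_000)
        fragment = seq[:700]  # 35% of the query
        rep = classify_unique_orfs([_feat("chr1", "CAND")],
                                   {"CAND": seq}, {"FRAG": fragment})
        assert rep.truly_absent == ["CAND"]

    def test_same_chromosome_match_flagged_for_inspection(self, rng):
        seq = random_seq(rng, 1_500)
        rep = classify_unique_orfs(
            [_feat("chr4", "CAND")], {"CAND": seq}, {"TWIN": seq},
            other_chromosomes={"TWIN": "chr4"})
        assert rep.inspect_same_chromosome == ["CAND"]

    def test_raising_identity_gate_never_shrinks_truly_absent(
            self, planted_orf_scenario):
        ann_a, ann_b, orfs_a, orfs_b = planted_orf_scenario
        nc = compare_gene_names(ann_a, ann_b)
        absent = {}
        for min_id in (0.85, 0.95, 0.99):
            rep = classify_unique_orfs(nc.unique_to_a, orfs_a, orfs_b,
                                       min_id=min_id)
            absent[min_id] = set(rep.truly_absent)
        assert absent[0.85] <= absent[0.95] <= absent[0.99]

    def test_missing_sequence_is_an_error(self):
        with pytest.raises(ValueError, match="no ORF sequence"):
            classify_unique_orfs([_feat("chr1", "GHOST")], {}, {"X": "ACGT" * 300})

    def test_identical_genomes_have_no_unique_sets(self, planted_orf_scenario):
        ann_a, _, orfs_a, _ = planted_orf_scenario
        nc = compare_gene_names(ann_a, list(ann_a))
        assert nc.unique_to_a == [] and nc.unique_to_b == []


@pytest.fixture
def repeat_genome(rng):
    consensus = random_seq(rng, 6_000)
    chrom = random_seq(rng, 5_000)
    positions = []
    for _ in range(7):
        positions.append(len(chrom))
        chrom += mutate_sequence(consensus, 0.03, rng) + random_seq(rng, 3_000)
    truncated_at = len(chrom)
    chrom += mutate_sequence(consensus[:1_500], 0.03, rng) + random_seq(rng, 3_000)
    g = Genome([(SequenceRecord("chr1", chrom), False)], name="g")
    return g, consensus, positions, truncated_at


class TestRepeatCensus:
    def test_planted_elements_counted(self, repeat_genome):
        g, consensus, positions, truncated_at = repeat_genome
        census = census_repeat_family(g, [SequenceRecord("TyA", consensus)])
        assert census.totals == {"TyA": 7}
        starts = sorted(s for _sid, s, _e, _i in census.locations["TyA"])
        assert all(abs(a - b) <= 100 for a, b in zip(starts, positions))

    def test_truncated_element_below_length_gate_excluded(self, repeat_genome):
        g, consensus, _positions, truncated_at = repeat_genome
        census = census_repeat_family(g, [SequenceRecord("TyA", consensus)])
        assert all(not (s <= truncated_at < e)
                   for _sid, s, e, _i in census.locations["TyA"])

    def test_probe_orientation_invariant(self, repeat_genome):
        g, consensus, _p, _t = repeat_genome
        fwd = census_repeat_family(g, [SequenceRecord("TyA", consensus)])
        rev = census_repeat_family(
            g, [SequenceRecord("TyA", revcomp(consensus))])
        assert {(s, e) for _sid, s, e, _i in fwd.locations["TyA"]} == \
            {(s, e) for _sid, s, e, _i in rev.locations["TyA"]}

    def test_two_probes_same_locus_merge(self, repeat_genome):
        g, consensus, _p, _t = repeat_genome
        census = census_repeat_family(
            g, [SequenceRecord("TyA", consensus),
                SequenceRecord("TyA_alt", consensus[200:5_800])])
        # TyA and TyA_alt are distinct families here; within one family the
        # same locus appears once
        assert census.totals["TyA"] == 7

    def test_empty_probe_set_rejected(self, repeat_genome):
        with pytest.raises(ValueError, match="empty"):
            census_repeat_family(repeat_genome[0], [])


class TestPanelAttribution:
    @pytest.fixture
    def panel(self, rng):
        strains = [Genome([(SequenceRecord(f"s{i}", random_seq(rng, 30_000)),
                            False)], name=f"strain{i}") for i in range(3)]
        return strains

    def test_source_strain_ranks_first_at_full_identity(self, panel):
        orf = SequenceRecord("orf", panel[1]["s1"].sequence[10_000:11_500])
        ranked = panel_attribution(orf, panel)
        assert ranked[0] == ("strain1", 1.0)

    def test_diverged_copy_still_attributed_to_source(self, rng, panel):
        src = panel[2]["s2"].sequence[5_000:6_500]
        orf = SequenceRecord("orf", mutate_sequence(src, 0.02, rng))
        ranked = panel_attribution(orf, panel)
        assert ranked[0][0] == "strain2"
        assert ranked[0][1] >= 0.95

    def test_low_coverage_everywhere_gives_empty_result(self, rng, panel):
        chunk = panel[0]["s0"].sequence[2_000:2_600]
        orf = SequenceRecord("orf", chunk + random_seq(rng, 1_400))
        assert panel_attribution(orf, panel) == []

    def test_empty_panel_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            panel_attribution(SequenceRecord("orf", random_seq(rng, 1_000)), [])
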