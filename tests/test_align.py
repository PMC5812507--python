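"""Anchor-chain aligner, one-to-one filtering and CIGAR error estimation."""

import numpy as np
import pytest

from nanocurate.align import (AlignmentBlock, ReadAlignment, align_contigs,
                              align_sequences, cigar_error_rate,
                              filter_one_to_one, map_read, parse_cigar)
from nanocurate.io_formats import Genome, SequenceRecord, revcomp
from conftest import random_seq


def _genome(*seqs):
    return Genome([(SequenceRecord(f"s{i}", s), False)
                   for i, s in enumerate(seqs)])


class TestAlignContigs:
    def test_self_alignment_full_identity(self, rng):
        seq = random_seq(rng, 10_000)
        g = _genome(seq)
        (b,) = [x for x in align_contigs(g, g) if x.qspan > 5_000]
        assert (b.qstart, b.qend, b.tstart, b.tend) == (0, 10_000, 0, 10_000)
        assert b.identity == 1.0

    def test_interior_deletion_counts_unmatched_columns(self, rng):
        """Deletion columns belong to block_len but not to matches; the
        expected counts come from an independent global aligner."""
        from Bio import Align

        target = random_seq(rng, 3_000)
        query = target[:1_500] + target[1_580:]  # 80 bp interior deletion
        (b,) = [x for x in align_contigs(_genome(query), _genome(target))
                if x.qspan > 1_000]
        aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                        mismatch_score=-2, open_gap_score=-3,
                                        extend_gap_score=0)
        aln = aligner.align(query, target)[0]
        counts = aln.counts()
        assert b.matches == counts.identities == 2_920
        assert b.block_len == counts.identities + counts.gaps == 3_000
        assert (b.qstart, b.qend, b.tstart, b.tend) == (0, 2_920, 0, 3_000)

    def test_reverse_complement_strand_symmetry(self, rng):
        seq = random_seq(rng, 8_000)
        g = _genome(seq)
        (fwd,) = [x for x in align_contigs(g, g) if x.qspan > 4_000]
        (rev,) = [x for x in
                  align_contigs(_genome(revcomp(seq)), g) if x.qspan > 4_000]
        assert rev.strand == "-"
        assert (rev.tstart, rev.tend) == (fwd.tstart, fwd.tend)
        assert rev.matches == fwd.matches

    def test_k_larger_than_shortest_sequence_rejected(self, rng):
        g = _genome(random_seq(rng, 1_000))
        with pytest.raises(ValueError, match="exceeds shortest"):
            align_contigs(_genome("ACGTACGTACGTA"), g, k=15)

    def test_self_coverage_of_repeat_free_genome(self, toy_genome):
        """Self-alignment covers >= 99% of every replicon at identity 1."""
        blocks = align_contigs(toy_genome, toy_genome)
        for rec, _ in toy_genome:
            cov = np.zeros(len(rec), dtype=bool)
            for b in blocks:
                if b.tid == rec.id and b.qid == rec.id and b.identity == 1.0:
                    cov[b.tstart:b.tend] = True
            assert cov.mean() >= 0.99


def _block(qid, qs, qe, tid, ts, te, matches, strand="+"):
    span = max(qe - qs, te - ts)
    return AlignmentBlock(qid=qid, qstart=qs, qend=qe, tid=tid, tstart=ts,
                          tend=te, strand=strand, matches=matches,
                          block_len=span)


def _greedy_reference(blocks, tol=50):
    """Independent restatement of the one-to-one rule: repeatedly take the
    highest-priority block conflicting with nothing kept, using plain
    pairwise overlap arithmetic."""
    order = sorted(blocks, key=lambda b: (-b.matches, -b.block_len, b.qid,
                                          b.tid, b.qstart, b.tstart))
    kept = []
    for b in order:
        ok = True
        for o in kept:
            if b.qid == o.qid and \
                    min(b.qend, o.qend) - max(b.qstart, o.qstart) > tol:
                ok = False
            if b.tid == o.tid and \
                    min(b.tend, o.tend) - max(b.tstart, o.tstart) > tol:
                ok = False
        if ok:
            kept.append(b)
    return sorted(kept, key=lambda b: (b.tid, b.tstart, b.qid, b.qstart))


class TestFilterOneToOne:
    def test_higher_match_block_wins_shared_target(self):
        a = _block("c1", 0, 1000, "t", 0, 1000, 900)
        b = _block("c2", 0, 1000, "t", 0, 1000, 800)
        assert filter_one_to_one([a, b]) == [a]

    def test_disjoint_blocks_all_kept(self):
        blocks = [_block("c1", 0, 500, "t", 0, 500, 450),
                  _block("c2", 0, 500, "t", 1000, 1500, 440)]
        assert filter_one_to_one(blocks) == blocks

    def test_empty_input(self):
        assert filter_one_to_one([]) == []

    def test_matches_independent_greedy_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 9))
            blocks = []
            for i in range(n):
                qs = int(rng.integers(0, 2_000))
                ts = int(rng.integers(0, 2_000))
                w = int(rng.integers(100, 900))
                blocks.append(_block(f"c{int(rng.integers(0, 3))}", qs, qs + w,
                                     f"t{int(rng.integers(0, 2))}", ts, ts + w,
                                     matches=int(w - rng.integers(0, 50))))
            assert filter_one_to_one(blocks) == _greedy_reference(blocks)

    def test_no_target_base_multiply_covered(self, rng):
        blocks = [_block("c%d" % i, 0, w, "t", ts, ts + w, w)
                  for i, (ts, w) in enumerate(
                      (int(rng.integers(0, 40_000)), int(rng.integers(200, 5_000)))
                      for _ in range(40))]
        kept = filter_one_to_one(blocks)
        cov = np.zeros(50_000, dtype=np.int32)
        for b in kept:
            cov[b.tstart:b.tend] += 1
        # pairwise overlaps of kept blocks are bounded by the tolerance
        assert (cov > 1).sum() <= 50 * len(kept)


class TestMapRead:
    def test_exact_read_maps_perfectly(self, rng):
        seq = random_seq(rng, 20_000)
        g = _genome(seq)
        aln = map_read(SequenceRecord("r", seq[4_000:9_000]), g)
        assert aln.cigar == "5000="
        assert aln.mapq == 60
        assert (aln.tstart, aln.tend) == (4_000, 9_000)

    def test_chimeric_read_single_arm_with_half_clip(self, rng):
        a, b = random_seq(rng, 30_000), random_seq(rng, 30_000)
        g = Genome([(SequenceRecord("cA", a), False),
                    (SequenceRecord("cB", b), False)])
        read = SequenceRecord("chimera", a[10_000:14_000] + b[20_000:24_000])
        aln = map_read(read, g)
        assert aln is not None
        clip = max(aln.clip_left, aln.clip_right)
        assert abs(clip - 4_000) <= 100

    def test_two_identical_loci_give_mapq_zero(self, rng):
        core = random_seq(rng, 5_000)
        seq = random_seq(rng, 3_000) + core + random_seq(rng, 3_000) \
            + core + random_seq(rng, 3_000)
        aln = map_read(SequenceRecord("r", core[1_000:4_000]), _genome(seq))
        assert aln.mapq == 0

    def test_cigar_column_sums_hold_for_noisy_reads(self, rng):
        from nanocurate.simulate import SimConfig, simulate_genome, simulate_reads

        cfg = SimConfig(n_chromosomes=2, chromosome_length_range=(30_000, 40_000),
                        n_repeat_elements=0, n_genes=10, read_coverage=3.0,
                        read_length_mean=6_000, seed=2)
        g, _, _ = simulate_genome(cfg)
        g.name = "g"
        reads, _ = simulate_reads([(g, 1.0)], cfg)
        n_mapped = 0
        for read in reads:
            aln = map_read(read, g)
            if aln is None:
                continue
            n_mapped += 1
            counts = {op: 0 for op in "=XIDSH"}
            for op, n in parse_cigar(aln.cigar):
                counts[op] += n
            assert counts["="] + counts["X"] + counts["D"] == aln.tend - aln.tstart
            assert counts["="] + counts["X"] + counts["I"] + counts["S"] \
                + counts["H"] == len(read)
            assert aln.clip_left + aln.clip_right == counts["S"] + counts["H"]
        assert n_mapped >= 0.9 * len(reads)


class TestCigarErrorRate:
    def test_hand_counted_example(self):
        aln = ReadAlignment("r", "t", 0, 97, "+", "90=5X3I2D", 60, 0, 0)
        stats = cigar_error_rate([aln])
        assert stats.error_rate == pytest.approx(10 / 100)
        assert (stats.mismatches, stats.insertions, stats.deletions) == (5, 3, 2)

    def test_clipping_and_mapq_gates(self):
        good = ReadAlignment("a", "t", 0, 100, "+", "100=", 60, 0, 0)
        clipped = ReadAlignment("b", "t", 0, 100, "+", "600S100=", 60, 600, 0)
        lowq = ReadAlignment("c", "t", 0, 100, "+", "100=", 0, 0, 0)
        stats = cigar_error_rate([good, clipped, lowq])
        assert stats.n_reads_used == 1
        assert stats.n_reads_filtered == 2

    def test_plain_m_cigar_rejected(self):
        aln = ReadAlignment("r", "t", 0, 100, "+", "100M", 60, 0, 0)
        with pytest.raises(ValueError, match="extended CIGAR"):
            cigar_error_rate([aln])


class TestAgainstMinimap2:
    def test_block_coordinates_agree_with_minimap2(self, rng, tmp_path):
        """Independent cross-check: a 30 kb pair with one rearranged segment
        yields the same aligned regions as minimap2 (within 100 bp)."""
        import shutil
        import subprocess

        if shutil.which("minimap2") is None:
            pytest.skip("minimap2 not on PATH")
        t = random_seq(rng, 30_000)
        # two distant target segments, the second reverse-complemented
        q = t[2_000:12_000] + revcomp(t[18_000:28_000])
        (tmp_path / "t.fa").write_text(f">t\n{t}\n")
        (tmp_path / "q.fa").write_text(f">q\n{q}\n")
        out = subprocess.run(
            ["minimap2", "-x", "asm5", str(tmp_path / "t.fa"),
             str(tmp_path / "q.fa")],
            capture_output=True, text=True, check=True).stdout
        mm2 = {(int(f[7]), int(f[8]), f[4])
               for f in (line.split("\t") for line in out.splitlines())}
        ours = {(b.tstart, b.tend, b.strand)
                for b in align_sequences(SequenceRecord("q", q),
                                         SequenceRecord("t", t))
                if b.tspan > 2_000}
        assert len(ours) == len(mm2) == 2
        for (ts, te, strand) in ours:
            assert any(abs(ts - ms) <= 100 and abs(te - me) <= 100
                       and strand == mstrand
                       for ms, me, mstrand in mm2)
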