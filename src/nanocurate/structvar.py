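"""Translocation breakpoint detection and chromosome-structure
heterogeneity calling from long reads.

A repeat-mediated reciprocal translocation exchanges the arms of two
chromosomes at a pair of homologous dispersed repeats. Because the
junction lies inside near-identical repeat copies, its position is only
defined to repeat resolution, and only a read long enough to span the
whole repeat plus unique flanking sequence on both sides can diagnose
which architecture the molecule it came from carried.

The workflow: detect candidate breakpoints from whole-genome alignment of
an assembly to a reference (:func:`detect_breakpoints`); build a dual
reference carrying both the normal and the translocated architectures
(:func:`build_dual_reference`); assign the nearest unique flanking genes
(:func:`find_flanking_unique_genes`); classify junction-spanning reads by
the architecture they support (:func:`classify_spanning_reads`); and call
the population verdict (:func:`call_heterogeneity`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .align import (DEFAULT_MAX_OCC, KmerIndex, _chains_for_sequence,
                    _cigar_counts, align_contigs, filter_one_to_one, map_read)
from .io_formats import FeatureRecord, Genome, SequenceRecord

__all__ = [
    "BreakpointPair",
    "ArchitectureSupport",
    "HeterogeneityCall",
    "detect_breakpoints",
    "build_dual_reference",
    "find_flanking_unique_genes",
    "classify_spanning_reads",
    "call_heterogeneity",
]


@dataclass
class BreakpointPair:
    """A candidate reciprocal translocation between two reference
    chromosomes.

    ``posA``/``posB`` are junction coordinates on the normal reference;
    when the junction falls inside a mediating repeat, ``repeatA`` and
    ``repeatB`` give the repeat intervals — the resolution to which the
    breakpoint is defined. Flanking genes are the nearest unique genes
    outside the mediating repeats.
    """

    chrA: str
    chrB: str
    posA: int
    posB: int
    repeatA: tuple[int, int] | None = None
    repeatB: tuple[int, int] | None = None
    flankA_left: FeatureRecord | None = None
    flankA_right: FeatureRecord | None = None
    flankB_left: FeatureRecord | None = None
    flankB_right: FeatureRecord | None = None

    def translocated_ids(self) -> tuple[str, str]:
        return (f"{self.chrA}-{self.chrB}", f"{self.chrB}-{self.chrA}")


@dataclass
class ArchitectureSupport:
    """Validated read support per chromosome architecture."""

    #: architecture name -> supporting read ids
    support: dict[str, list[str]] = field(default_factory=dict)
    ambiguous: list[str] = field(default_factory=list)
    validation_dropped: list[str] = field(default_factory=list)
    n_candidates: int = 0
    n_scanned: int = 0

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.support.items()}

    def side_counts(self) -> tuple[int, int]:
        """(normal-architecture supporters, translocated supporters)."""
        normal = sum(len(v) for k, v in self.support.items()
                     if k.startswith("normal"))
        trans = sum(len(v) for k, v in self.support.items()
                    if k.startswith("transloc"))
        return normal, trans


def detect_breakpoints(assembly: Genome, reference: Genome,
                       min_block: int = 10_000, merge_tol: int = 50_000,
                       overlap_tolerance: int = 10_000,
                       k: int = 15, max_gap: int = 500,
                       blocks=None) -> list[BreakpointPair]:
    """Detect inter-chromosomal junctions from whole-genome alignment.

    One-to-one-filtered blocks of every assembly contig are ordered along
    the contig; a junction where two consecutive blocks (each at least
    ``min_block`` bp) map to different reference chromosomes yields a
    breakpoint pair at the facing block boundaries. The two junctions of a
    reciprocal event (within ``merge_tol`` on both chromosomes) are merged
    into a single pair.

    ``overlap_tolerance`` is repeat-scale rather than the default 50 bp:
    at a repeat-mediated junction both arms align through the homologous
    repeat copy, so the two chimeric blocks legitimately share the repeat
    span on the contig.
    """
    if blocks is None:
        blocks = align_contigs(assembly, reference, k=k, max_gap=max_gap)
    blocks = filter_one_to_one(blocks, overlap_tolerance=overlap_tolerance)

    raw: list[BreakpointPair] = []
    by_contig: dict[str, list] = {}
    for b in blocks:
        by_contig.setdefault(b.qid, []).append(b)
    for _qid, bl in sorted(by_contig.items()):
        bl.sort(key=lambda b: b.qstart)
        bl = [b for b in bl if b.qspan >= min_block]
        for left, right in zip(bl, bl[1:]):
            if left.tid == right.tid:
                continue
            posA = left.tend if left.strand == "+" else left.tstart
            posB = right.tstart if right.strand == "+" else right.tend
            raw.append(BreakpointPair(chrA=left.tid, chrB=right.tid,
                                      posA=posA, posB=posB))

    events: list[BreakpointPair] = []
    for bp in raw:
        merged = False
        for i, ev in enumerate(events):
            # same pair seen from the other contig: chrA/chrB swapped
            if (ev.chrA == bp.chrB and ev.chrB == bp.chrA
                    and abs(ev.posA - bp.posB) <= merge_tol
                    and abs(ev.posB - bp.posA) <= merge_tol):
                events[i] = replace(ev, posA=(ev.posA + bp.posB) // 2,
                                    posB=(ev.posB + bp.posA) // 2)
                merged = True
                break
            if (ev.chrA == bp.chrA and ev.chrB == bp.chrB
                    and abs(ev.posA - bp.posA) <= merge_tol
                    and abs(ev.posB - bp.posB) <= merge_tol):
                merged = True
                break
        if not merged:
            events.append(bp)
    return events


def build_dual_reference(reference: Genome, bp: BreakpointPair) -> Genome:
    """Reference carrying both architectures: every original replicon plus
    the two translocated chromosomes chrA-chrB and chrB-chrA."""
    sa = reference[bp.chrA].sequence
    sb = reference[bp.chrB].sequence
    if not (0 < bp.posA < len(sa)) or not (0 < bp.posB < len(sb)):
        raise ValueError("breakpoint coordinates outside chromosome bounds")
    ab_id, ba_id = bp.translocated_ids()
    replicons = list(reference.replicons)
    replicons.append((SequenceRecord(ab_id, sa[:bp.posA] + sb[bp.posB:]), False))
    replicons.append((SequenceRecord(ba_id, sb[:bp.posB] + sa[bp.posA:]), False))
    return Genome(replicons, name=f"{reference.name or 'reference'}+dual")


def find_flanking_unique_genes(bp: BreakpointPair,
                               annotations: Sequence[FeatureRecord],
                               repeat_locations: Sequence[FeatureRecord] | None = None,
                               max_search: int = 50_000) -> BreakpointPair:
    """Assign the nearest unique genes flanking each junction.

    Searching outward from the mediating repeat boundary (or the junction
    coordinate when no repeat contains it), a flank gene must not
    intersect any repeat location and its name must occur exactly once in
    the annotation. Failure to find one within ``max_search`` bp is a hard
    error naming the side.
    """
    genes = [f for f in annotations if f.type == "gene" and f.gene_name]
    if repeat_locations is None:
        repeat_locations = [f for f in annotations
                            if f.type != "gene"]
    name_counts: dict[str, int] = {}
    for g in genes:
        name_counts[g.gene_name] = name_counts.get(g.gene_name, 0) + 1

    def _repeat_at(chrom: str, pos: int) -> tuple[int, int]:
        for r in repeat_locations:
            if r.seqid == chrom and r.start <= pos <= r.end:
                return (r.start, r.end)
        return (pos, pos)

    def _clear_of_repeats(g: FeatureRecord) -> bool:
        return all(g.end <= r.start or g.start >= r.end
                   for r in repeat_locations if r.seqid == g.seqid)

    def _nearest(chrom: str, boundary: int, side: str) -> FeatureRecord:
        pool = [g for g in genes if g.seqid == chrom
                and name_counts[g.gene_name] == 1 and _clear_of_repeats(g)]
        if side == "left":
            pool = [g for g in pool if g.end <= boundary
                    and boundary - g.end <= max_search]
            pool.sort(key=lambda g: boundary - g.end)
        else:
            pool = [g for g in pool if g.start >= boundary
                    and g.start - boundary <= max_search]
            pool.sort(key=lambda g: g.start - boundary)
        if not pool:
            raise ValueError(
                f"no unique flanking gene within {max_search} bp "
                f"{side} of {chrom}:{boundary}")
        return pool[0]

    repA = bp.repeatA or _repeat_at(bp.chrA, bp.posA)
    repB = bp.repeatB or _repeat_at(bp.chrB, bp.posB)
    return replace(
        bp, repeatA=repA, repeatB=repB,
        flankA_left=_nearest(bp.chrA, repA[0], "left"),
        flankA_right=_nearest(bp.chrA, repA[1], "right"),
        flankB_left=_nearest(bp.chrB, repB[0], "left"),
        flankB_right=_nearest(bp.chrB, repB[1], "right"),
    )


def _architecture_table(bp: BreakpointPair) -> dict[str, dict]:
    """Per-architecture replicon, junction interval and required flank spans.

    The junction interval is the mediating repeat span on that replicon: a
    supporting read must align contiguously across it and into both flank
    genes. Coordinates of the B-side flanks on the translocated replicons
    are shifted by the arm exchange.
    """
    if None in (bp.repeatA, bp.repeatB, bp.flankA_left, bp.flankA_right,
                bp.flankB_left, bp.flankB_right):
        raise ValueError("breakpoint needs repeats and flank genes assigned "
                         "(run find_flanking_unique_genes)")
    ab_id, ba_id = bp.translocated_ids()
    shift_ab = bp.posA - bp.posB  # chrB coordinate -> chrA-B coordinate
    shift_ba = bp.posB - bp.posA
    return {
        "normal_A": {
            "replicon": bp.chrA, "junction": bp.repeatA,
            "left": (bp.flankA_left.start, bp.flankA_left.end),
            "right": (bp.flankA_right.start, bp.flankA_right.end)},
        "normal_B": {
            "replicon": bp.chrB, "junction": bp.repeatB,
            "left": (bp.flankB_left.start, bp.flankB_left.end),
            "right": (bp.flankB_right.start, bp.flankB_right.end)},
        "transloc_AB": {
            "replicon": ab_id,
            "junction": (bp.repeatA[0], bp.repeatB[1] + shift_ab),
            "left": (bp.flankA_left.start, bp.flankA_left.end),
            "right": (bp.flankB_right.start + shift_ab,
                      bp.flankB_right.end + shift_ab)},
        "transloc_BA": {
            "replicon": ba_id,
            "junction": (bp.repeatB[0], bp.repeatA[1] + shift_ba),
            "left": (bp.flankB_left.start, bp.flankB_left.end),
            "right": (bp.flankA_right.start + shift_ba,
                      bp.flankA_right.end + shift_ba)},
    }


def classify_spanning_reads(reads: Sequence[SequenceRecord],
                            dual_reference: Genome, bp: BreakpointPair,
                            min_flank_overlap: int = 100,
                            k: int = 15, max_gap: int = 500,
                            tie_margin: float = 0.01,
                            validate: bool = True) -> ArchitectureSupport:
    """Classify reads by the chromosome architecture they span.

    A read supports an architecture iff its best alignment is a single
    contiguous alignment on that architecture's replicon that covers the
    junction and overlaps both flanking unique genes by at least
    ``min_flank_overlap`` bp. Reads whose best alignments tie across
    architectures (within ``tie_margin`` relative match difference) are
    ambiguous and never assigned. A validation pass re-aligns every
    supporter to the full dual reference and drops any whose best hit
    moves off the supported replicon.
    """
    arch = _architecture_table(bp)
    arch_genome = Genome(
        [(dual_reference[d["replicon"]], False) for d in arch.values()],
        name="architectures")
    arch_index = KmerIndex(arch_genome, k=k)
    junction_by_replicon = {d["replicon"]: d["junction"] for d in arch.values()}
    arch_by_replicon = {d["replicon"]: name for name, d in arch.items()}

    full_index = KmerIndex(dual_reference, k=k) if validate else None

    # one single-replicon genome + index per architecture, built once
    per_arch: dict[str, tuple[Genome, KmerIndex]] = {}
    for name, d in arch.items():
        sub = Genome([(arch_genome[d["replicon"]], False)])
        per_arch[name] = (sub, KmerIndex(sub, k=k))

    result = ArchitectureSupport(support={name: [] for name in arch})
    chain_slack = 50  # chain endpoints sit within a few bp of alignment ends
    for read in reads:
        result.n_scanned += 1
        if len(read) < k:
            continue
        # one anchor-chain pass over the four architecture replicons
        chains = _chains_for_sequence(read.sequence, arch_index, max_gap,
                                      DEFAULT_MAX_OCC)
        best_chain: dict[str, object] = {}
        for ch in chains:
            name = arch_by_replicon[arch_index.ids[ch.replicon]]
            cur = best_chain.get(name)
            if cur is None or ch.n_anchors > cur.n_anchors:
                best_chain[name] = ch
        # candidate gate: a chain touching some architecture's junction
        is_candidate = any(
            ch.tstart < junction_by_replicon[arch[name]["replicon"]][1]
            and ch.tend > junction_by_replicon[arch[name]["replicon"]][0]
            for name, ch in best_chain.items())
        if not is_candidate:
            continue
        result.n_candidates += 1

        def _chain_spans(name, ch) -> bool:
            d = arch[name]
            return (ch.tstart <= d["left"][1] - min_flank_overlap + chain_slack
                    and ch.tend >= d["right"][0] + min_flank_overlap - chain_slack)

        spanning_potential = [name for name, ch in best_chain.items()
                              if _chain_spans(name, ch)]
        counts = sorted((ch.n_anchors for ch in best_chain.values()),
                        reverse=True)
        if not spanning_potential:
            # cannot support anything; flag exact repeat-interior ties
            if len(counts) > 1 and counts[1] >= (1 - tie_margin) * counts[0]:
                result.ambiguous.append(read.id)
            continue

        # base-level alignment for every architecture still in contention
        max_n = counts[0]
        scored: list[tuple[int, str, object]] = []
        for name, ch in best_chain.items():
            if ch.n_anchors < 0.7 * max_n:
                continue
            sub, sub_index = per_arch[name]
            aln = map_read(read, sub, k=k, max_gap=max_gap, index=sub_index)
            if aln is None:
                continue
            scored.append((_cigar_counts(aln.cigar)["="], name, aln))
        if not scored:
            continue
        scored.sort(key=lambda x: (-x[0], x[1]))
        best_m, best_name, best_aln = scored[0]
        if len(scored) > 1 and scored[1][0] >= (1 - tie_margin) * best_m:
            result.ambiguous.append(read.id)
            continue
        d = arch[best_name]
        spans = (best_aln.tstart <= d["left"][1] - min_flank_overlap
                 and best_aln.tend >= d["right"][0] + min_flank_overlap)
        if not spans:
            continue
        if validate:
            full = map_read(read, dual_reference, k=k, max_gap=max_gap,
                            index=full_index)
            if full is None or full.tid != d["replicon"]:
                result.validation_dropped.append(read.id)
                continue
        result.support[best_name].append(read.id)
    return result


@dataclass
class HeterogeneityCall:
    """Population-level verdict from architecture support counts."""

    verdict: str  # heterogeneous | single_architecture | inconclusive
    normal_reads: int
    translocated_reads: int
    counts: dict[str, int]


def call_heterogeneity(support: ArchitectureSupport,
                       min_reads: int = 1) -> HeterogeneityCall:
    """Call whether the sequenced population is structurally heterogeneous.

    Heterogeneous iff at least ``min_reads`` validated supporters exist
    for both a normal and a translocated architecture; single_architecture
    iff exactly one side is supported; inconclusive otherwise.
    """
    normal, trans = support.side_counts()
    if normal >= min_reads and trans >= min_reads:
        verdict = "heterogeneous"
    elif normal >= min_reads or trans >= min_reads:
        verdict = "single_architecture"
    else:
        verdict = "inconclusive"
    return HeterogeneityCall(verdict=verdict, normal_reads=normal,
                             translocated_reads=trans,
                             counts=support.counts)
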