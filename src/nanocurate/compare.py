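"""Gained and lost sequence between two assemblies.

The comparison follows alignment-coordinate arithmetic: contigs of one
assembly (at least ``min_contig`` bp) are aligned to the other, overlapping
alignments of the same contig are collapsed into per-contig footprints, the
footprints are unioned, and the complement of the union over the target
assembly is the sequence present only there. Gene annotations whose span
falls at least half inside those unaligned regions are the gained (or
lost) genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import AlignmentBlock, align_contigs, filter_one_to_one
from .io_formats import FeatureRecord, Genome, IntervalSet

__all__ = [
    "GainLossReport",
    "collapse_alignments",
    "gained_sequence",
    "lost_sequence",
]


@dataclass
class GainLossReport:
    """Unaligned ("gained" or "lost") coordinates of one assembly of a pair."""

    direction: str  # "gained" | "lost"
    intervals: IntervalSet
    genes: list[FeatureRecord] = field(default_factory=list)
    n_contigs_used: int = 0

    @property
    def total_bp(self) -> int:
        return self.intervals.total_length()

    @property
    def gene_names(self) -> list[str]:
        return [g.gene_name for g in self.genes]


def collapse_alignments(blocks: Sequence[AlignmentBlock],
                        min_contig: int = 1_000,
                        query_lengths: dict[str, int] | None = None,
                        ) -> IntervalSet:
    """Aligned footprint on the target: per-contig overlapping target
    intervals merged, then unioned over contigs.

    Blocks whose query contig is shorter than ``min_contig`` are dropped;
    contig lengths come from the blocks' ``qlen`` or from
    ``query_lengths``. Multimapped contigs contribute all their footprints.
    """
    footprint = IntervalSet()
    for b in blocks:
        qlen = b.qlen
        if qlen is None and query_lengths is not None:
            qlen = query_lengths.get(b.qid)
        if qlen is not None and qlen < min_contig:
            continue
        footprint.add(b.tid, b.tstart, b.tend)
    return footprint


def _gain_loss(query_assembly: Genome, target_assembly: Genome,
               target_annotations: Iterable[FeatureRecord],
               direction: str,
               exclude_seqids: Sequence[str] = (),
               blocks: Sequence[AlignmentBlock] | None = None,
               min_contig: int = 1_000,
               gene_overlap_fraction: float = 0.5,
               one_to_one: bool = False,
               k: int = 15, max_gap: int = 500,
               ) -> GainLossReport:
    target_lengths = target_assembly.lengths()
    annotations = list(target_annotations)
    for f in annotations:
        if f.seqid not in target_lengths:
            raise ValueError(
                f"annotation {f.gene_name or f.feature_id!r} on unknown "
                f"sequence {f.seqid!r}")

    if blocks is None:
        blocks = align_contigs(query_assembly, target_assembly,
                               k=k, max_gap=max_gap)
    if one_to_one:
        blocks = filter_one_to_one(blocks)

    query_lengths = query_assembly.lengths()
    footprint = collapse_alignments(blocks, min_contig=min_contig,
                                    query_lengths=query_lengths)
    excl = set(exclude_seqids)
    lengths = {sid: L for sid, L in target_lengths.items() if sid not in excl}
    # restrict the footprint to the retained replicons before complementing
    restricted = IntervalSet(
        {sid: footprint.intervals(sid) for sid in lengths
         if footprint.intervals(sid)})
    unaligned = restricted.complement(lengths)

    genes = []
    for f in annotations:
        if f.type != "gene" or f.seqid in excl:
            continue
        ov = unaligned.overlap_length(f.seqid, f.start, f.end)
        if ov >= gene_overlap_fraction * len(f):
            genes.append(f)

    used = {b.qid for b in blocks
            if (b.qlen or query_lengths.get(b.qid, min_contig)) >= min_contig}
    return GainLossReport(direction=direction, intervals=unaligned,
                          genes=genes, n_contigs_used=len(used))


def gained_sequence(short_assembly: Genome, long_assembly: Genome,
                    long_annotations: Iterable[FeatureRecord],
                    exclude_seqids: Sequence[str] = (),
                    **kwargs) -> GainLossReport:
    """Sequence present in ``long_assembly`` that no contig (>= 1 Kbp) of
    ``short_assembly`` aligns to, with the gene annotations it carries.

    Replicons named in ``exclude_seqids`` (organellar/plasmid contigs that
    the other assembly never attempted) are left out of the report.
    Keyword arguments: ``blocks`` (precomputed alignments), ``min_contig``,
    ``gene_overlap_fraction``, ``one_to_one``, ``k``, ``max_gap``.
    """
    return _gain_loss(short_assembly, long_assembly, long_annotations,
                      "gained", exclude_seqids, **kwargs)


def lost_sequence(short_assembly: Genome, long_assembly: Genome,
                  short_annotations: Iterable[FeatureRecord],
                  exclude_seqids: Sequence[str] = (),
                  **kwargs) -> GainLossReport:
    """Sequence of ``short_assembly`` that no contig of ``long_assembly``
    aligns to — the symmetric counterpart of :func:`gained_sequence` with
    the roles of the assemblies swapped."""
    return _gain_loss(long_assembly, short_assembly, short_annotations,
                      "lost", exclude_seqids, **kwargs)
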