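"""Assembly curation steps as reproducible algorithms.

Long-read assemblers leave characteristic artifacts that assembly projects
traditionally fix by hand: circular replicons represented as linear contigs
with a duplicated terminal overlap, chromosomes split at long repeats that
a spanning read could bridge, and low-coverage artifact tails carrying
duplicated telomeric caps. This module implements those fixes as explicit
operations, each returning a :class:`CurationAction` audit record that
makes the edit reproducible from its evidence.

Telomere-cap assessment (:func:`detect_telomere_caps`) scores assembly
completeness by aligning telomere repeat probes to the terminal windows of
every contig — a proxy for "assembled up to the chromosome end".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .align import (KmerIndex, ReadAlignment, align_sequences, map_read)
from .io_formats import FeatureRecord, Genome, SequenceRecord, revcomp

__all__ = [
    "TelomereStatus",
    "CurationAction",
    "trim_circular_overlap",
    "join_over_repeat",
    "detect_telomere_caps",
    "summarize_caps",
    "trim_artifact_tail",
]


@dataclass
class CurationAction:
    """Audit record of one curation edit."""

    action: str  # circular_trim | join_spanned | join_gap | tail_trim | none
    contigs: list[str]
    coordinates: dict[str, int] = field(default_factory=dict)
    evidence: dict = field(default_factory=dict)


@dataclass
class TelomereStatus:
    """Telomere-cap assessment of one contig.

    ``left_intervals``/``right_intervals`` hold every probe match inside
    the terminal windows (several when caps are duplicated); the flags are
    true when at least one qualifying match exists on that side.
    """

    contig_id: str
    left_cap: bool
    right_cap: bool
    left_intervals: list[tuple[int, int]] = field(default_factory=list)
    right_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_caps_total(self) -> int:
        return len(self.left_intervals) + len(self.right_intervals)


# ---------------------------------------------------------------------------
# circular-overlap trimming


def trim_circular_overlap(contig: SequenceRecord, min_overlap: int = 1_000,
                          min_identity: float = 0.95, end_slack: int = 50,
                          ) -> tuple[SequenceRecord, CurationAction]:
    """Remove the duplicated terminal overlap of a circular-candidate contig.

    The contig prefix is aligned against its suffix; a terminal self-overlap
    of at least ``min_overlap`` bp at ``min_identity`` or better (anchored
    within ``end_slack`` bp of both contig ends) marks one duplicated copy,
    which is removed. Without a qualifying overlap the contig is returned
    unchanged with a no-op action.
    """
    L = len(contig)
    w = L // 2
    if w < min_overlap:
        return contig, CurationAction("none", [contig.id],
                                      evidence={"reason": "contig too short"})
    prefix = SequenceRecord("prefix", contig.sequence[:w])
    suffix = SequenceRecord("suffix", contig.sequence[L - w:])
    blocks = align_sequences(prefix, suffix)
    best = None
    for b in blocks:
        if (b.strand == "+" and b.qstart <= end_slack
                and b.tend >= w - end_slack
                and b.qspan >= min_overlap and b.identity >= min_identity):
            if best is None or b.matches > best.matches:
                best = b
    if best is None:
        return contig, CurationAction("none", [contig.id],
                                      evidence={"reason": "no qualifying overlap"})
    cut = (L - w) + best.tstart - best.qstart
    trimmed = SequenceRecord(contig.id, contig.sequence[:cut],
                             contig.description)
    action = CurationAction(
        "circular_trim", [contig.id],
        coordinates={"cut": cut, "original_length": L,
                     "trimmed_length": cut},
        evidence={"overlap_length": L - cut, "identity": best.identity},
    )
    return trimmed, action


# ---------------------------------------------------------------------------
# repeat-spanning contig joining


def join_over_repeat(contigA: SequenceRecord, contigB: SequenceRecord,
                     reads: Sequence[SequenceRecord],
                     min_overlap: int = 2_000,
                     flank_genes: tuple[FeatureRecord, FeatureRecord] | None = None,
                     min_flank_overlap: int = 100, gap_len: int = 500,
                     end_slack: int = 100, window: int = 30_000,
                     min_identity: float = 0.9,
                     ) -> tuple[SequenceRecord, CurationAction]:
    """Join two contigs that share a terminal (repeat) overlap.

    The end of ``contigA`` must overlap the start of ``contigB`` by at
    least ``min_overlap`` bp. If at least one read aligns contiguously
    across the overlap and covers both flanking genes by
    ``min_flank_overlap`` bp, the contigs are merged without duplicating
    the overlap (``join_spanned``); otherwise the full contigs are
    concatenated around a run of ``gap_len`` N characters (``join_gap``),
    mirroring a gap join across an unresolvable repeat.

    ``flank_genes`` gives the nearest unique genes left of the overlap (on
    ``contigA`` coordinates) and right of it (on ``contigB`` coordinates).
    """
    wa = min(len(contigA), window)
    wb = min(len(contigB), window)
    tailA = SequenceRecord("tailA", contigA.sequence[len(contigA) - wa:])
    headB = SequenceRecord("headB", contigB.sequence[:wb])
    blocks = align_sequences(tailA, headB)
    best = None
    for b in blocks:
        if (b.strand == "+" and b.qend >= wa - end_slack
                and b.tstart <= end_slack and b.identity >= min_identity):
            if best is None or b.matches > best.matches:
                best = b
    if best is None:
        raise ValueError(
            f"no terminal overlap detected between {contigA.id} and {contigB.id}")
    overlap = best.tend - best.tstart  # bp of contigB start covered by A's tail
    if overlap < min_overlap:
        raise ValueError(
            f"terminal overlap {overlap} bp below min_overlap={min_overlap}")

    merged_seq = contigA.sequence + contigB.sequence[overlap:]
    joined_id = f"{contigA.id}+{contigB.id}"

    supporters: list[str] = []
    if flank_genes is not None and reads:
        flank_left, flank_right = flank_genes
        shift = len(contigA) - overlap  # contigB -> merged coordinates
        left_end = flank_left.end
        right_start = flank_right.start + shift
        candidate = Genome([(SequenceRecord(joined_id, merged_seq), False)])
        index = KmerIndex(candidate)
        for read in reads:
            aln = map_read(read, candidate, index=index)
            if aln is None:
                continue
            if (aln.tstart <= left_end - min_flank_overlap
                    and aln.tend >= right_start + min_flank_overlap):
                supporters.append(read.id)

    if supporters:
        joined = SequenceRecord(joined_id, merged_seq)
        action = CurationAction(
            "join_spanned", [contigA.id, contigB.id],
            coordinates={"overlap": overlap, "joined_length": len(joined)},
            evidence={"overlap_length": overlap, "identity": best.identity,
                      "supporting_reads": supporters},
        )
    else:
        joined = SequenceRecord(
            joined_id, contigA.sequence + "N" * gap_len + contigB.sequence)
        action = CurationAction(
            "join_gap", [contigA.id, contigB.id],
            coordinates={"gap_length": gap_len, "joined_length": len(joined)},
            evidence={"overlap_length": overlap, "identity": best.identity,
                      "supporting_reads": []},
        )
    return joined, action


# ---------------------------------------------------------------------------
# telomere caps


def _probe_matches(window_seq: str, probes: Sequence[SequenceRecord],
                   min_probe_cov: float, min_identity: float,
                   max_matches: int = 6, merge_gap: int = 200,
                   ) -> list[tuple[int, int]]:
    """Non-overlapping probe matches within one terminal window.

    Each probe (both orientations, full and half length down to
    ``min_probe_cov``) is aligned infix-style; qualifying matches are
    masked out and the search repeats, so duplicated caps yield several
    intervals. Matches closer than ``merge_gap`` are merged (a long tandem
    array is one cap, not many).
    """
    seq = window_seq
    found: list[tuple[int, int]] = []
    queries: list[str] = []
    for p in probes:
        for orient in (p.sequence, revcomp(p.sequence)):
            for frac in (1.0, 0.75, max(min_probe_cov, 0.5)):
                n = int(len(orient) * frac)
                if n >= 20:
                    queries.append(orient[:n])
    for _ in range(max_matches):
        best = None
        for q in queries:
            res = edlib.align(q, seq, mode="HW", task="locations")
            ident = 1.0 - res["editDistance"] / len(q)
            if ident >= min_identity and res["locations"]:
                s, e = res["locations"][0]
                if best is None or ident * len(q) > best[0]:
                    best = (ident * len(q), s, e + 1)
        if best is None:
            break
        _, s, e = best
        found.append((s, e))
        seq = seq[:s] + "#" * (e - s) + seq[e:]
    if not found:
        return []
    found.sort()
    merged = [found[0]]
    for s, e in found[1:]:
        ls, le = merged[-1]
        if s - le <= merge_gap:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def detect_telomere_caps(genome: Genome, probes: Sequence[SequenceRecord],
                         window: int = 15_000, min_probe_cov: float = 0.5,
                         min_identity: float = 0.8,
                         ) -> list[TelomereStatus]:
    """Assess completeness of each replicon by its terminal telomere caps.

    Probe alignments inside the outer ``window`` bp of each end are
    counted; a cap is called when an alignment covers at least
    ``min_probe_cov`` of the probe at ``min_identity`` or better.
    """
    if not probes:
        raise ValueError("empty telomere probe set")
    statuses = []
    for rec, _circ in genome:
        w = min(window, len(rec))
        left = _probe_matches(rec.sequence[:w], probes, min_probe_cov,
                              min_identity)
        right_off = len(rec) - w
        right = [(s + right_off, e + right_off)
                 for s, e in _probe_matches(rec.sequence[right_off:], probes,
                                            min_probe_cov, min_identity)]
        # a match visible in both windows (short contig) counts once, left
        if right_off < w:
            right = [iv for iv in right if iv not in left]
        statuses.append(TelomereStatus(
            contig_id=rec.id, left_cap=bool(left), right_cap=bool(right),
            left_intervals=left, right_intervals=right))
    return statuses


def summarize_caps(statuses: Sequence[TelomereStatus]) -> dict[str, int]:
    """Counts of contigs with both, one, or no telomere caps."""
    both = sum(1 for s in statuses if s.left_cap and s.right_cap)
    one = sum(1 for s in statuses if s.left_cap != s.right_cap)
    none = sum(1 for s in statuses if not s.left_cap and not s.right_cap)
    return {"both_caps": both, "one_cap": one, "no_caps": none}


# ---------------------------------------------------------------------------
# artifact-tail trimming


def trim_artifact_tail(contig: SequenceRecord, caps: TelomereStatus,
                       read_alignments: Sequence[ReadAlignment],
                       low_cov_fraction: float = 0.1,
                       ) -> tuple[SequenceRecord, CurationAction]:
    """Remove an unsupported artifact tail beyond a duplicated telomere cap.

    When one contig end carries two or more cap matches, the sequence past
    the innermost cap is an assembly artifact if raw-read coverage there
    falls below ``low_cov_fraction`` of the contig-wide mean; the contig is
    truncated immediately after the innermost cap. A single cap is a
    healthy chromosome end and yields a no-op.
    """
    relevant = [a for a in read_alignments if a.tid == contig.id]
    L = len(contig)
    seq = contig.sequence

    def _absorb_right(cap_s: int, cap_e: int, word: int = 12) -> int:
        """Extend the cap end through trailing array residue: bases whose
        ``word``-mers still occur inside the matched cap belong to it."""
        cap = seq[cap_s:cap_e]
        e = cap_e
        while e < L and seq[e - word + 1:e + 1] in cap:
            e += 1
        return e

    def _absorb_left(cap_s: int, cap_e: int, word: int = 12) -> int:
        cap = seq[cap_s:cap_e]
        s = cap_s
        while s > 0 and seq[s - 1:s + word - 1] in cap:
            s -= 1
        return s

    for side, intervals in (("right", caps.right_intervals),
                            ("left", caps.left_intervals)):
        if len(intervals) < 2:
            continue
        if not relevant:
            raise ValueError(f"{contig.id}: coverage unavailable "
                             "(no mapped reads)")
        cov = np.zeros(L, dtype=np.int64)
        for a in relevant:
            cov[a.tstart:a.tend] += 1
        mean_cov = float(cov.mean())
        if side == "right":
            inner_s, inner_e = min(intervals, key=lambda iv: iv[1])
            innermost_end = _absorb_right(inner_s, inner_e)
            tail = cov[innermost_end:]
            if len(tail) and float(tail.mean()) < low_cov_fraction * mean_cov:
                trimmed = SequenceRecord(contig.id,
                                         contig.sequence[:innermost_end],
                                         contig.description)
                return trimmed, CurationAction(
                    "tail_trim", [contig.id],
                    coordinates={"cut": innermost_end, "original_length": L},
                    evidence={"side": "right",
                              "tail_mean_coverage": float(tail.mean()),
                              "contig_mean_coverage": mean_cov,
                              "n_caps": len(intervals)},
                )
        else:
            inner_s, inner_e = max(intervals, key=lambda iv: iv[0])
            innermost_start = _absorb_left(inner_s, inner_e)
            head = cov[:innermost_start]
            if len(head) and float(head.mean()) < low_cov_fraction * mean_cov:
                trimmed = SequenceRecord(contig.id,
                                         contig.sequence[innermost_start:],
                                         contig.description)
                return trimmed, CurationAction(
                    "tail_trim", [contig.id],
                    coordinates={"cut": innermost_start, "original_length": L},
                    evidence={"side": "left",
                              "head_mean_coverage": float(head.mean()),
                              "contig_mean_coverage": mean_cov,
                              "n_caps": len(intervals)},
                )
    return contig, CurationAction("none", [contig.id],
                                  evidence={"reason": "no duplicated low-coverage cap tail"})
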