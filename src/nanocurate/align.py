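"""Minimal anchor-and-chain aligner and CIGAR-based error-rate estimation.

The aligner finds exact k-mer anchors on both strands, chains colinear
anchors (bounded gap on both axes, consistent diagonal drift), and closes
each chain into a gapped alignment by global base-level alignment of the
chained segments (edlib), yielding an extended CIGAR that distinguishes
matches (``=``) from mismatches (``X``).

Two front ends share this machinery:

* :func:`align_contigs` — genome vs genome, producing
  :class:`AlignmentBlock` records (the functional analogue of a
  ``nucmer --maxmatch`` run);
* :func:`map_read` — a single read vs a genome, producing a
  :class:`ReadAlignment` with soft-clipped unanchored termini and a
  two-level mapping-quality proxy.

:func:`filter_one_to_one` selects a non-conflicting best subset of blocks
(the delta-filter analogue) and :func:`cigar_error_rate` pools per-column
error counts over mapped reads under mapping-quality and clipping gates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
from intervaltree import IntervalTree

from .io_formats import Genome, SequenceRecord, revcomp

__all__ = [
    "AlignmentBlock",
    "ReadAlignment",
    "CigarErrorStats",
    "KmerIndex",
    "align_contigs",
    "align_sequences",
    "filter_one_to_one",
    "map_read",
    "cigar_error_rate",
    "parse_cigar",
]

DEFAULT_K = 15
DEFAULT_MAX_GAP = 500
DEFAULT_MIN_CHAIN_ANCHORS = 3
DEFAULT_MAX_OCC = 100


@dataclass
class AlignmentBlock:
    """One gapped local alignment between a query and a target interval.

    Coordinates are 0-based half-open on the forward strand of each
    sequence; for ``strand == '-'`` the reverse complement of the query
    interval aligns to the target interval. ``block_len`` counts alignment
    columns including indels, so ``identity = matches / block_len`` is
    conservative under indel-rich alignments.
    """

    qid: str
    qstart: int
    qend: int
    tid: str
    tstart: int
    tend: int
    strand: str
    matches: int
    block_len: int
    qlen: int | None = None
    tlen: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.qend - self.qstart > self.block_len:
            raise ValueError("query span exceeds block_len")
        if self.tend - self.tstart > self.block_len:
            raise ValueError("target span exceeds block_len")
        if self.matches > self.block_len:
            raise ValueError("matches exceed block_len")

    @property
    def identity(self) -> float:
        return self.matches / self.block_len if self.block_len else 0.0

    @property
    def qspan(self) -> int:
        return self.qend - self.qstart

    @property
    def tspan(self) -> int:
        return self.tend - self.tstart


_CIGAR_RE = re.compile(r"(\d+)([=XIDSHM])")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse an extended CIGAR string into (op, length) pairs."""
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def _cigar_counts(cigar: str) -> dict[str, int]:
    counts = {op: 0 for op in "=XIDSHM"}
    for op, n in parse_cigar(cigar):
        counts[op] += n
    return counts


@dataclass
class ReadAlignment:
    """A read mapped to a reference with an extended CIGAR.

    The CIGAR is written in alignment orientation (for ``strand == '-'``
    it describes the reverse complement of the read against the forward
    target); soft clips at either end cover the unaligned read termini in
    that same orientation. mapq is a two-level proxy: 60 for confidently
    placed reads, 0 for ambiguous ones.
    """

    read_id: str
    tid: str
    tstart: int
    tend: int
    strand: str
    cigar: str
    mapq: int
    clip_left: int
    clip_right: int

    def __post_init__(self) -> None:
        c = _cigar_counts(self.cigar)
        if c["M"]:
            # tolerated at construction (externally imported alignments);
            # rejected by cigar_error_rate, which needs =/X resolution
            if c["M"] + c["="] + c["X"] + c["D"] != self.tend - self.tstart:
                raise ValueError(
                    f"read {self.read_id}: CIGAR target span mismatch")
            return
        if c["="] + c["X"] + c["D"] != self.tend - self.tstart:
            raise ValueError(
                f"read {self.read_id}: CIGAR target span "
                f"{c['='] + c['X'] + c['D']} != {self.tend - self.tstart}")

    @property
    def read_length(self) -> int:
        c = _cigar_counts(self.cigar)
        return c["="] + c["X"] + c["I"] + c["S"] + c["H"]

    @property
    def aligned_read_length(self) -> int:
        c = _cigar_counts(self.cigar)
        return c["="] + c["X"] + c["I"]


@dataclass
class CigarErrorStats:
    """Pooled per-column error counts over a set of read alignments."""

    n_reads_used: int
    n_reads_filtered: int
    mismatches: int
    insertions: int
    deletions: int
    aligned_columns: int

    @property
    def error_rate(self) -> float:
        if self.aligned_columns == 0:
            return 0.0
        return (self.mismatches + self.insertions + self.deletions) / self.aligned_columns


# ---------------------------------------------------------------------------
# k-mer machinery

_BASE_VALS = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_VALS[_b] = _i


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers of ``seq``; windows containing non-ACGT
    characters get code -1."""
    vals = _BASE_VALS[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(vals) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + np.where(vals[j:n + j] < 0, 0, vals[j:n + j])
    bad = (vals < 0).astype(np.int64)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    invalid = (cbad[k:] - cbad[:-k]) > 0
    codes[invalid] = -1
    return codes


class KmerIndex:
    """Sorted exact k-mer index over the replicons of a genome."""

    def __init__(self, genome: Genome, k: int = DEFAULT_K):
        if k < 1:
            raise ValueError("k must be positive")
        shortest = min(len(rec) for rec, _ in genome)
        if k > shortest:
            raise ValueError(
                f"k={k} exceeds shortest target sequence ({shortest} bp)")
        self.k = k
        self.genome = genome
        self.ids = genome.ids
        lengths = [len(rec) for rec, _ in genome]
        # replicon r occupies global positions [offsets[r], offsets[r] + len)
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        codes_parts, pos_parts = [], []
        for r, (rec, _) in enumerate(genome):
            c = _kmer_codes(rec.sequence, k)
            valid = c >= 0
            codes_parts.append(c[valid])
            pos_parts.append(np.nonzero(valid)[0] + self.offsets[r])
        codes = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.int64)
        pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self._sorted_codes = codes[order]
        self._sorted_pos = pos[order]

    def replicon_of(self, gpos: np.ndarray) -> np.ndarray:
        """Replicon index for each global position."""
        return np.searchsorted(self.offsets, gpos, side="right") - 1

    def anchors(self, seq: str, max_occ: int = DEFAULT_MAX_OCC
                ) -> tuple[np.ndarray, np.ndarray]:
        """All exact k-mer matches of ``seq`` against the index.

        Returns (query positions, global target positions); k-mers with more
        than ``max_occ`` occurrences in the target are skipped (repeat
        saturation guard).
        """
        qc = _kmer_codes(seq, self.k)
        valid = qc >= 0
        qpos_all = np.nonzero(valid)[0]
        qc = qc[valid]
        lo = np.searchsorted(self._sorted_codes, qc, side="left")
        hi = np.searchsorted(self._sorted_codes, qc, side="right")
        occ = hi - lo
        keep = (occ > 0) & (occ <= max_occ)
        lo, occ, qpos_all = lo[keep], occ[keep], qpos_all[keep]
        total = int(occ.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qpos = np.repeat(qpos_all, occ)
        starts = np.repeat(lo, occ)
        within = np.arange(total) - np.repeat(
            np.concatenate([[0], np.cumsum(occ)[:-1]]), occ)
        tpos = self._sorted_pos[starts + within]
        return qpos, tpos


# ---------------------------------------------------------------------------
# chaining


@dataclass
class _Chain:
    qstart: int
    qend: int  # half-open, includes +k of last anchor
    tstart: int
    tend: int
    n_anchors: int
    replicon: int
    strand: str


def _chain_anchors(qpos: np.ndarray, tpos: np.ndarray, k: int, max_gap: int,
                   replicon: int, strand: str) -> list[_Chain]:
    """Chain anchors of one (replicon, strand) group into colinear runs.

    Anchors are clustered by diagonal (tolerance ``max_gap``, the maximum
    indel drift allowed inside one alignment), then scanned in query order;
    a gap > ``max_gap`` on either axis or a target-coordinate reversal
    closes the chain.
    """
    if len(qpos) == 0:
        return []
    diag = tpos - qpos
    order = np.lexsort((qpos, diag))
    qpos, tpos, diag = qpos[order], tpos[order], diag[order]
    breaks = np.nonzero(np.diff(diag) > max_gap)[0] + 1
    chains: list[_Chain] = []
    for lo, hi in zip(np.concatenate([[0], breaks]),
                      np.concatenate([breaks, [len(qpos)]])):
        q, t = qpos[lo:hi], tpos[lo:hi]
        o = np.lexsort((t, q))
        q, t = q[o], t[o]
        dq, dt = np.diff(q), np.diff(t)
        if len(q) == 1 or bool(np.all((dq <= max_gap) & (dt > -k) & (dt <= max_gap))):
            chains.append(_Chain(int(q[0]), int(q[-1]) + k,
                                 int(t[0]), int(t[-1]) + k,
                                 len(q), replicon, strand))
            continue
        # slow path: greedy scan with explicit gap/monotonicity checks
        cq0, ct0, lq, lt, n = int(q[0]), int(t[0]), int(q[0]), int(t[0]), 1
        for i in range(1, len(q)):
            qi, ti = int(q[i]), int(t[i])
            if qi - lq <= max_gap and -k < ti - lt <= max_gap:
                lq, lt, n = qi, ti, n + 1
            elif qi - lq > max_gap:
                chains.append(_Chain(cq0, lq + k, ct0, lt + k, n, replicon, strand))
                cq0, ct0, lq, lt, n = qi, ti, qi, ti, 1
            # else: off-chain anchor (target reversal) — skip
        chains.append(_Chain(cq0, lq + k, ct0, lt + k, n, replicon, strand))
    return chains


def _chains_for_sequence(seq: str, index: KmerIndex, max_gap: int,
                         max_occ: int) -> list[_Chain]:
    """All chains of ``seq`` (both strands) against the indexed genome.

    Minus-strand chains carry query coordinates of the reverse-complemented
    sequence; callers convert back.
    """
    chains: list[_Chain] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        qpos, tpos = index.anchors(s, max_occ=max_occ)
        if len(qpos) == 0:
            continue
        repl = index.replicon_of(tpos)
        order = np.argsort(repl, kind="stable")
        qpos, tpos, repl = qpos[order], tpos[order], repl[order]
        bounds = np.nonzero(np.diff(repl))[0] + 1
        for lo, hi in zip(np.concatenate([[0], bounds]),
                          np.concatenate([bounds, [len(repl)]])):
            r = int(repl[lo])
            local_t = tpos[lo:hi] - index.offsets[r]
            chains.extend(_chain_anchors(qpos[lo:hi], local_t, index.k,
                                         max_gap, r, strand))
    return chains


def _edlib_extended(query: str, target: str) -> tuple[str, int, int, int, int, int]:
    """Global alignment; returns (cigar, matches, mismatches, ins, dels, columns).

    Columns where either character is N are never counted as matches.
    """
    res = edlib.align(query, target, mode="NW", task="path")
    cigar = res["cigar"]
    c = _cigar_counts(cigar)
    matches = c["="]
    if "N" in query or "N" in target:
        qi = ti = 0
        matches = 0
        for op, n in parse_cigar(cigar):
            if op == "=":
                matches += sum(
                    1 for j in range(n)
                    if query[qi + j] != "N" and target[ti + j] != "N")
            if op in "=XI":
                qi += n
            if op in "=XD":
                ti += n
    columns = c["="] + c["X"] + c["I"] + c["D"]
    return cigar, matches, c["X"], c["I"], c["D"], columns


def _extend_flank(qflank: str, tflank: str, match: int = 1, penalty: int = 2,
                  ) -> tuple[int, int, int, int]:
    """Score-trimmed extension of an alignment into unanchored flanks.

    Both flanks run outward from the block edge. They are globally aligned
    and the alignment is walked outward, scoring +1 per match and -2 per
    mismatch/indel column; the extension stops at the score maximum
    (X-drop-style trimming), so homologous flank sequence — e.g. a tandem
    repeat array too k-mer-saturated to anchor — is absorbed while
    non-homologous sequence is not.

    Returns (query consumed, target consumed, matches, columns).
    """
    if len(qflank) < 10 or len(tflank) < 10:
        return 0, 0, 0, 0
    cigar, *_ = _edlib_extended(qflank, tflank)
    score = best = 0
    qi = ti = matches = columns = 0
    best_state = (0, 0, 0, 0)
    for op, n in parse_cigar(cigar):
        if op == "=":
            for j in range(n):
                if qflank[qi + j] == "N" or tflank[ti + j] == "N":
                    score -= penalty
                else:
                    score += match
                    if score > best:
                        best = score
                        best_state = (qi + j + 1, ti + j + 1,
                                      matches + j + 1, columns + j + 1)
            qi += n
            ti += n
            matches += n
            columns += n
        else:
            score -= penalty * n
            if op in ("X", "I"):
                qi += n
            if op in ("X", "D"):
                ti += n
            columns += n
        if score < best - 100:  # hopeless: deep in non-homologous sequence
            break
    return best_state


def align_sequences(query: SequenceRecord, target: SequenceRecord,
                    k: int = DEFAULT_K, min_chain_anchors: int = DEFAULT_MIN_CHAIN_ANCHORS,
                    max_gap: int = DEFAULT_MAX_GAP, max_occ: int = DEFAULT_MAX_OCC,
                    ) -> list[AlignmentBlock]:
    """Align one query sequence against one target sequence."""
    return align_contigs(Genome([(query, False)]), Genome([(target, False)]),
                         k=k, min_chain_anchors=min_chain_anchors,
                         max_gap=max_gap, max_occ=max_occ)


def align_contigs(query: Genome, target: Genome, k: int = DEFAULT_K,
                  min_chain_anchors: int = DEFAULT_MIN_CHAIN_ANCHORS,
                  max_gap: int = DEFAULT_MAX_GAP,
                  max_occ: int = DEFAULT_MAX_OCC,
                  extend: int = 2_000,
                  index: KmerIndex | None = None) -> list[AlignmentBlock]:
    """Align every query replicon against a whole target genome.

    Produces one :class:`AlignmentBlock` per anchor chain with at least
    ``min_chain_anchors`` anchors; repeat copies yield one block each
    (maxmatch-style multi-mapping, no one-to-one filtering here). Each
    block is extended up to ``extend`` bp beyond its outermost anchors by
    score-trimmed base-level alignment, which recovers homologous flanks
    whose k-mers are too repetitive to anchor (telomere arrays).

    A pre-built :class:`KmerIndex` over ``target`` may be passed to amortise
    index construction across calls.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if index is None:
        index = KmerIndex(target, k=k)
    elif index.k != k:
        raise ValueError("index k does not match requested k")
    shortest_q = min(len(rec) for rec, _ in query)
    if k > shortest_q:
        raise ValueError(f"k={k} exceeds shortest query sequence ({shortest_q} bp)")

    blocks: list[AlignmentBlock] = []
    for rec, _ in query:
        qlen = len(rec)
        rc = revcomp(rec.sequence)
        for ch in _chains_for_sequence(rec.sequence, index, max_gap, max_occ):
            if ch.n_anchors < min_chain_anchors:
                continue
            tid = index.ids[ch.replicon]
            trec = target[tid]
            oriented = rec.sequence if ch.strand == "+" else rc
            qseq = oriented[ch.qstart:ch.qend]
            tseq = trec.sequence[ch.tstart:ch.tend]
            _, matches, *_rest, columns = _edlib_extended(qseq, tseq)
            qs, qe, ts, te = ch.qstart, ch.qend, ch.tstart, ch.tend
            if extend:
                qc, tc, m, cols = _extend_flank(
                    oriented[max(0, qs - extend):qs][::-1],
                    trec.sequence[max(0, ts - extend):ts][::-1])
                qs, ts, matches, columns = qs - qc, ts - tc, matches + m, columns + cols
                qc, tc, m, cols = _extend_flank(
                    oriented[qe:qe + extend],
                    trec.sequence[te:te + extend])
                qe, te, matches, columns = qe + qc, te + tc, matches + m, columns + cols
            if ch.strand == "+":
                qstart, qend = qs, qe
            else:
                qstart, qend = qlen - qe, qlen - qs
            blocks.append(AlignmentBlock(
                qid=rec.id, qstart=qstart, qend=qend,
                tid=tid, tstart=ts, tend=te,
                strand=ch.strand, matches=matches, block_len=columns,
                qlen=qlen, tlen=len(trec),
            ))
    return blocks


def filter_one_to_one(blocks: Sequence[AlignmentBlock],
                      overlap_tolerance: int = 50) -> list[AlignmentBlock]:
    """Greedy best one-to-one filtering of alignment blocks.

    Blocks are visited by descending (matches, block_len) with lexicographic
    (qid, tid) tie-break; a block is kept iff it overlaps no already-kept
    block by more than ``overlap_tolerance`` bp on either its query or its
    target interval. The kept set is returned in target order.
    """
    ranked = sorted(
        blocks,
        key=lambda b: (-b.matches, -b.block_len, b.qid, b.tid,
                       b.qstart, b.tstart))
    qtrees: dict[str, IntervalTree] = {}
    ttrees: dict[str, IntervalTree] = {}
    kept: list[AlignmentBlock] = []
    for b in ranked:
        conflict = False
        for tree, key, lo, hi in (
            (qtrees.get(b.qid), b.qid, b.qstart, b.qend),
            (ttrees.get(b.tid), b.tid, b.tstart, b.tend),
        ):
            if tree is None:
                continue
            for iv in tree.overlap(lo, hi):
                if min(iv.end, hi) - max(iv.begin, lo) > overlap_tolerance:
                    conflict = True
                    break
            if conflict:
                break
        if conflict:
            continue
        kept.append(b)
        qtrees.setdefault(b.qid, IntervalTree()).addi(b.qstart, b.qend)
        ttrees.setdefault(b.tid, IntervalTree()).addi(b.tstart, b.tend)
    return sorted(kept, key=lambda b: (b.tid, b.tstart, b.qid, b.qstart))


def map_read(read: SequenceRecord, target: Genome, k: int = DEFAULT_K,
             max_gap: int = DEFAULT_MAX_GAP, max_occ: int = DEFAULT_MAX_OCC,
             index: KmerIndex | None = None,
             mapq_margin: float = 0.05) -> ReadAlignment | None:
    """Map one read to a genome; returns None if no anchor chain is found.

    The best chain (most anchors) is closed with base-level alignment of
    the chained span; unanchored read termini become soft clips. mapq is 60
    when the best chain's anchor count exceeds the best chain at any other
    locus by more than ``mapq_margin`` (5%), else 0.
    """
    if index is None:
        index = KmerIndex(target, k=k)
    if len(read) < index.k:
        raise ValueError(f"read {read.id}: shorter than k={index.k}")
    chains = _chains_for_sequence(read.sequence, index, max_gap, max_occ)
    if not chains:
        return None
    chains.sort(key=lambda c: (-c.n_anchors, c.replicon, c.tstart))
    best = chains[0]
    second = 0
    for ch in chains[1:]:
        if ch.replicon == best.replicon and ch.strand == best.strand:
            ov = min(ch.tend, best.tend) - max(ch.tstart, best.tstart)
            if ov > 0.5 * (ch.tend - ch.tstart):
                continue  # fragment of the same locus, not a rival placement
        second = ch.n_anchors
        break
    mapq = 60 if best.n_anchors > (1 + mapq_margin) * second else 0

    tid = index.ids[best.replicon]
    tseq = target[tid].sequence
    oriented = read.sequence if best.strand == "+" else revcomp(read.sequence)
    body, *_counts = _edlib_extended(oriented[best.qstart:best.qend],
                                     tseq[best.tstart:best.tend])
    clip_left = best.qstart
    clip_right = len(read) - best.qend
    cigar = ""
    if clip_left:
        cigar += f"{clip_left}S"
    cigar += body
    if clip_right:
        cigar += f"{clip_right}S"
    return ReadAlignment(
        read_id=read.id, tid=tid, tstart=best.tstart, tend=best.tend,
        strand=best.strand, cigar=cigar, mapq=mapq,
        clip_left=clip_left, clip_right=clip_right,
    )


def cigar_error_rate(alignments: Iterable[ReadAlignment], min_mapq: int = 1,
                     max_clip: int = 500) -> CigarErrorStats:
    """Pooled per-column error rate from extended CIGARs.

    Reads with mapq below ``min_mapq`` or more than ``max_clip`` nt of
    soft/hard clipping on either end are excluded (guards against erroneous
    placements in repetitive regions). The rate is
    (X + I + D) / (= + X + I + D) pooled over the remaining reads.
    """
    used = filtered = mism = ins = dels = columns = 0
    for aln in alignments:
        if aln.mapq < min_mapq or aln.clip_left > max_clip or aln.clip_right > max_clip:
            filtered += 1
            continue
        c = _cigar_counts(aln.cigar)
        if c["M"]:
            raise ValueError(
                f"read {aln.read_id}: CIGAR contains 'M'; extended CIGAR required")
        used += 1
        mism += c["X"]
        ins += c["I"]
        dels += c["D"]
        columns += c["="] + c["X"] + c["I"] + c["D"]
    return CigarErrorStats(
        n_reads_used=used, n_reads_filtered=filtered,
        mismatches=mism, insertions=ins, deletions=dels,
        aligned_columns=columns,
    )
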