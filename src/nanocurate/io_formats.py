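"""Readers/writers for the standard formats the pipeline touches.

All coordinates inside the package are 0-based half-open. Formats that use
1-based inclusive coordinates (GFF3, the nucmer ``show-coords``-style TSV)
are converted exactly once, here, on read and on write. BED and PAF are
already 0-based half-open and pass through unchanged.

Sequences are DNA over ``{A, C, G, T, N}``; lower-case input is upper-cased
on read (soft-masking is not interpreted). ``N`` is legal — gap joins emit
runs of it — but the aligner never counts it as a match.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "Genome",
    "FeatureRecord",
    "IntervalSet",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_gff3",
    "write_gff3",
    "read_paf",
    "write_paf",
    "read_coords_tsv",
    "write_coords_tsv",
    "read_bed",
    "write_bed",
    "revcomp",
]

_VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named DNA sequence (one FASTA/FASTQ record)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-ACGTN characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """An ordered collection of replicons, each optionally circular.

    A yeast-like genome holds linear chromosomes plus circular replicons
    (mitochondrial genome, 2-micron plasmid) whose assembled contig
    representation is linear and may carry a duplicated terminal overlap.
    """

    replicons: list[tuple[SequenceRecord, bool]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [rec.id for rec, _ in self.replicons]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate replicon id(s): {dup}")

    @classmethod
    def from_records(
        cls, records: Iterable[SequenceRecord], name: str = "",
        circular: Iterable[str] = (),
    ) -> "Genome":
        circ = set(circular)
        return cls([(r, r.id in circ) for r in records], name=name)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec, _ in self.replicons]

    @property
    def records(self) -> list[SequenceRecord]:
        return [rec for rec, _ in self.replicons]

    def __len__(self) -> int:
        return len(self.replicons)

    def __iter__(self) -> Iterator[tuple[SequenceRecord, bool]]:
        return iter(self.replicons)

    def __contains__(self, seqid: str) -> bool:
        return any(rec.id == seqid for rec, _ in self.replicons)

    def __getitem__(self, seqid: str) -> SequenceRecord:
        for rec, _ in self.replicons:
            if rec.id == seqid:
                return rec
        raise KeyError(seqid)

    def is_circular(self, seqid: str) -> bool:
        for rec, circ in self.replicons:
            if rec.id == seqid:
                return circ
        raise KeyError(seqid)

    def lengths(self) -> dict[str, int]:
        return {rec.id: len(rec) for rec, _ in self.replicons}

    def total_length(self) -> int:
        return sum(len(rec) for rec, _ in self.replicons)


@dataclass
class FeatureRecord:
    """One annotated feature (gene, repeat element, ...).

    Coordinates are internal 0-based half-open; ``read_gff3``/``write_gff3``
    convert from/to the GFF3 1-based inclusive convention.
    """

    seqid: str
    start: int
    end: int
    strand: str
    type: str = "gene"
    gene_name: str = ""
    feature_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id or self.gene_name!r}: "
                             f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id or self.gene_name!r}: invalid "
                f"span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class IntervalSet:
    """Per-sequence sorted, pairwise-disjoint 0-based half-open intervals.

    The carrier of "aligned", "gained" and "lost" coordinates. All mutating
    input is normalised: overlapping or touching intervals are merged.
    """

    def __init__(self, intervals: dict[str, Sequence[tuple[int, int]]] | None = None):
        self._ivs: dict[str, list[tuple[int, int]]] = {}
        if intervals:
            for seqid, pairs in intervals.items():
                for s, e in pairs:
                    self.add(seqid, s, e)

    def add(self, seqid: str, start: int, end: int) -> None:
        if start < 0 or start >= end:
            raise ValueError(f"invalid interval [{start}, {end})")
        ivs = self._ivs.setdefault(seqid, [])
        ivs.append((int(start), int(end)))
        self._ivs[seqid] = _merge(ivs)

    def seqids(self) -> list[str]:
        return sorted(self._ivs)

    def intervals(self, seqid: str) -> list[tuple[int, int]]:
        return list(self._ivs.get(seqid, []))

    def items(self) -> Iterator[tuple[str, list[tuple[int, int]]]]:
        for seqid in self.seqids():
            yield seqid, list(self._ivs[seqid])

    def total_length(self, seqid: str | None = None) -> int:
        if seqid is not None:
            return sum(e - s for s, e in self._ivs.get(seqid, []))
        return sum(e - s for ivs in self._ivs.values() for s, e in ivs)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out = IntervalSet()
        for src in (self, other):
            for seqid, ivs in src.items():
                for s, e in ivs:
                    out.add(seqid, s, e)
        return out

    def complement(self, lengths: dict[str, int]) -> "IntervalSet":
        """Uncovered coordinates of each sequence in ``lengths``."""
        out = IntervalSet()
        for seqid, length in lengths.items():
            pos = 0
            for s, e in self._ivs.get(seqid, []):
                if e > length:
                    raise ValueError(
                        f"{seqid}: interval [{s}, {e}) exceeds length {length}")
                if s > pos:
                    out.add(seqid, pos, s)
                pos = max(pos, e)
            if pos < length:
                out.add(seqid, pos, length)
        return out

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = IntervalSet()
        for seqid in self._ivs:
            a = self._ivs[seqid]
            b = other._ivs.get(seqid, [])
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s < e:
                    out.add(seqid, s, e)
                if a[i][1] < b[j][1]:
                    i += 1
                else:
                    j += 1
        return out

    def overlap_length(self, seqid: str, start: int, end: int) -> int:
        """Total bp of [start, end) covered by this set on ``seqid``."""
        return sum(
            max(0, min(e, end) - max(s, start))
            for s, e in self._ivs.get(seqid, [])
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._ivs == other._ivs

    def __repr__(self) -> str:
        n = sum(len(v) for v in self._ivs.values())
        return f"IntervalSet({n} intervals, {self.total_length()} bp)"


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching intervals; returns sorted disjoint list."""
    ivs = sorted(ivs)
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = out[-1]
        if s <= le:
            out[-1] = (ls, max(le, e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, name: str = "", circular: Iterable[str] = ()) -> Genome:
    """Read a (possibly gzipped) FASTA file into a :class:`Genome`.

    Replicon ids listed in ``circular`` are flagged circular.
    """
    records = []
    seen: set[str] = set()
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq), rec.description))
    return Genome.from_records(records, name=name or Path(path).stem,
                               circular=circular)


def write_fasta(genome: Genome | Iterable[SequenceRecord], path: str | Path,
                width: int = 80) -> None:
    recs = genome.records if isinstance(genome, Genome) else list(genome)
    with _open(path, "wt") as fh:
        for rec in recs:
            fh.write(f">{rec.id}" + (f" {rec.description}" if rec.description else "") + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read reads from (possibly gzipped) FASTQ; base qualities are dropped —
    no operation in this package consumes them."""
    out = []
    seen: set[str] = set()
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            out.append(SequenceRecord(rec.id, str(rec.seq), rec.description))
    return out


def write_fastq(reads: Iterable[SequenceRecord], path: str | Path,
                quality_char: str = "I") -> None:
    with _open(path, "wt") as fh:
        for rec in reads:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{quality_char * len(rec)}\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path, lengths: dict[str, int] | None = None
              ) -> list[FeatureRecord]:
    """Read GFF3 features, converting 1-based inclusive to 0-based half-open.

    If ``lengths`` is given, features outside sequence bounds are a hard
    error. Attributes ``Name`` and ``ID`` populate ``gene_name`` and
    ``feature_id``.
    """
    feats: list[FeatureRecord] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, "
                                 f"got {len(fields)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            s1, e1 = int(start), int(end)
            if not (1 <= s1 <= e1):
                raise ValueError(f"{path}:{lineno}: invalid span {s1}..{e1}")
            if lengths is not None:
                if seqid not in lengths:
                    raise ValueError(f"{path}:{lineno}: unknown seqid {seqid!r}")
                if e1 > lengths[seqid]:
                    raise ValueError(
                        f"{path}:{lineno}: end {e1} exceeds length of {seqid}")
            attr = _parse_attrs(attrs)
            feats.append(FeatureRecord(
                seqid=seqid, start=s1 - 1, end=e1, strand=strand, type=ftype,
                gene_name=attr.get("Name", ""), feature_id=attr.get("ID", ""),
            ))
    return feats


def _parse_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def write_gff3(features: Iterable[FeatureRecord], path: str | Path,
               source: str = "nanocurate") -> None:
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = []
            if f.feature_id:
                attrs.append(f"ID={f.feature_id}")
            if f.gene_name:
                attrs.append(f"Name={f.gene_name}")
            fh.write("\t".join([
                f.seqid, source, f.type, str(f.start + 1), str(f.end),
                ".", f.strand, ".", ";".join(attrs) or ".",
            ]) + "\n")


# ---------------------------------------------------------------------------
# PAF / coords TSV / BED (alignment and interval interchange)


def read_paf(path: str | Path):
    """Read minimap2-style PAF into :class:`~nanocurate.align.AlignmentBlock`
    records. PAF is already 0-based half-open; no conversion is applied."""
    from .align import AlignmentBlock

    blocks = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: PAF needs ≥ 12 columns")
            strand = f[4]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            qlen, qstart, qend = int(f[1]), int(f[2]), int(f[3])
            tlen, tstart, tend = int(f[6]), int(f[7]), int(f[8])
            if not (0 <= qstart < qend <= qlen) or not (0 <= tstart < tend <= tlen):
                raise ValueError(f"{path}:{lineno}: coordinates out of bounds")
            blocks.append(AlignmentBlock(
                qid=f[0], qstart=qstart, qend=qend,
                tid=f[5], tstart=tstart, tend=tend,
                strand=strand, matches=int(f[9]), block_len=int(f[10]),
                qlen=qlen, tlen=tlen,
            ))
    return blocks


def write_paf(blocks, path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for b in blocks:
            fh.write("\t".join(map(str, [
                b.qid, b.qlen if b.qlen is not None else b.qend,
                b.qstart, b.qend, b.strand,
                b.tid, b.tlen if b.tlen is not None else b.tend,
                b.tstart, b.tend, b.matches, b.block_len, 60,
            ])) + "\n")


_COORDS_COLS = ["qid", "qstart", "qend", "tid", "tstart", "tend",
                "strand", "matches", "block_len"]


def read_coords_tsv(path: str | Path):
    """Read a ``show-coords``-style TSV (1-based inclusive on both axes),
    converting to internal 0-based half-open coordinates.

    Columns: qid, qstart, qend, tid, tstart, tend, strand, matches, block_len.
    A header line repeating the column names is permitted and skipped.
    """
    from .align import AlignmentBlock

    blocks = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] == "qid":
                continue
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            strand = f[6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            qs, qe, ts, te = int(f[1]), int(f[2]), int(f[4]), int(f[5])
            if not (1 <= qs <= qe) or not (1 <= ts <= te):
                raise ValueError(f"{path}:{lineno}: coordinates out of bounds")
            blocks.append(AlignmentBlock(
                qid=f[0], qstart=qs - 1, qend=qe,
                tid=f[3], tstart=ts - 1, tend=te,
                strand=strand, matches=int(f[7]), block_len=int(f[8]),
            ))
    return blocks


def write_coords_tsv(blocks, path: str | Path) -> None:
    """Write AlignmentBlocks as the 1-based inclusive coords TSV."""
    with _open(path, "wt") as fh:
        fh.write("\t".join(_COORDS_COLS) + "\n")
        for b in blocks:
            fh.write("\t".join(map(str, [
                b.qid, b.qstart + 1, b.qend, b.tid, b.tstart + 1, b.tend,
                b.strand, b.matches, b.block_len,
            ])) + "\n")


def read_bed(path: str | Path) -> IntervalSet:
    out = IntervalSet()
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs ≥ 3 columns")
            out.add(f[0], int(f[1]), int(f[2]))
    return out


def write_bed(interval_set: IntervalSet, path: str | Path) -> None:
    """Write an IntervalSet as 0-based half-open BED3."""
    with _open(path, "wt") as fh:
        for seqid, ivs in interval_set.items():
            for s, e in ivs:
                fh.write(f"{seqid}\t{s}\t{e}\n")
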