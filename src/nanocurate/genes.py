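"""Gene-set comparison between two annotated genomes.

Four operations cover the comparative-genomics questions a new assembly
raises: which gene names are unique to either genome
(:func:`compare_gene_names`); which of those candidates are genuinely
absent from the other genome versus divergent or renamed copies
(:func:`classify_unique_orfs`); how many copies of a dispersed repeat
family the genome carries (:func:`census_repeat_family`); and which strain
of a user-supplied panel a given ORF most resembles
(:func:`panel_attribution`).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import align_contigs, KmerIndex
from .io_formats import FeatureRecord, Genome, SequenceRecord

__all__ = [
    "NameComparison",
    "UniqueGeneReport",
    "RepeatCensus",
    "compare_gene_names",
    "classify_unique_orfs",
    "census_repeat_family",
    "panel_attribution",
    "extract_orfs",
]

_DUP_SUFFIX = re.compile(r"(?:_dup\d*|_copy\d*)$", re.IGNORECASE)


def _norm_name(name: str) -> str:
    """Case-insensitive gene-name key with duplicate-marker suffixes
    (``_dup2``, ``_copy3``) stripped; empty for unnamed features."""
    return _DUP_SUFFIX.sub("", name.strip()).upper()


def extract_orfs(genome: Genome, annotations: Sequence[FeatureRecord],
                 ) -> dict[str, str]:
    """Nucleotide sequence of every named gene, keyed by normalised name.
    Minus-strand genes are returned reverse complemented."""
    from .io_formats import revcomp

    out: dict[str, str] = {}
    for f in annotations:
        if f.type != "gene" or not f.gene_name:
            continue
        seq = genome[f.seqid].sequence[f.start:f.end]
        out[_norm_name(f.gene_name)] = seq if f.strand == "+" else revcomp(seq)
    return out


@dataclass
class NameComparison:
    """Strict name-based gene-set difference between two annotations."""

    unique_to_a: list[FeatureRecord]
    unique_to_b: list[FeatureRecord]
    n_unnamed_a: int
    n_unnamed_b: int
    #: names present in both genomes but on different chromosomes
    relocated: list[str] = field(default_factory=list)


def compare_gene_names(annot_a: Sequence[FeatureRecord],
                       annot_b: Sequence[FeatureRecord],
                       per_chromosome: bool = True) -> NameComparison:
    """Multiset difference of gene names, per chromosome when flagged.

    Names are compared case-insensitively with duplicate-marker suffixes
    stripped; unnamed features never match and are only counted. With
    ``per_chromosome`` a gene present in both genomes but on different
    chromosomes appears in both unique lists and is flagged as relocated.
    """
    genes_a = [f for f in annot_a if f.type == "gene"]
    genes_b = [f for f in annot_b if f.type == "gene"]
    n_unnamed_a = sum(1 for f in genes_a if not _norm_name(f.gene_name))
    n_unnamed_b = sum(1 for f in genes_b if not _norm_name(f.gene_name))

    def _key(f: FeatureRecord):
        return ((f.seqid, _norm_name(f.gene_name)) if per_chromosome
                else (_norm_name(f.gene_name),))

    counts_a = Counter(_key(f) for f in genes_a if _norm_name(f.gene_name))
    counts_b = Counter(_key(f) for f in genes_b if _norm_name(f.gene_name))

    uniq_a, uniq_b = [], []
    taken_a: Counter = Counter()
    for f in genes_a:
        k = _key(f)
        if not _norm_name(f.gene_name):
            continue
        taken_a[k] += 1
        if taken_a[k] > counts_b.get(k, 0):
            uniq_a.append(f)
    taken_b: Counter = Counter()
    for f in genes_b:
        k = _key(f)
        if not _norm_name(f.gene_name):
            continue
        taken_b[k] += 1
        if taken_b[k] > counts_a.get(k, 0):
            uniq_b.append(f)

    relocated = []
    if per_chromosome:
        names_a = {_norm_name(f.gene_name) for f in uniq_a}
        names_b = {_norm_name(f.gene_name) for f in uniq_b}
        relocated = sorted(names_a & names_b)
    return NameComparison(uniq_a, uniq_b, n_unnamed_a, n_unnamed_b, relocated)


@dataclass
class UniqueGeneReport:
    """Classification of name-unique candidate ORFs of one genome against
    the full ORF set of the other.

    ``truly_absent`` genes have no detectable cross-alignment at
    ``min_cov`` coverage or better at any identity; ``homologue_map``
    records qualifying matches (both gates passed); ``diverged_matches``
    records detectable relatives whose identity falls below the gate —
    present in some form, but too divergent to call homologues.
    """

    truly_absent: list[str]
    homologue_map: dict[str, list[tuple[str, float, float]]]
    diverged_matches: dict[str, list[tuple[str, float, float]]]
    inspect_same_chromosome: list[str]
    min_cov: float
    min_id: float


def classify_unique_orfs(candidates: Sequence[FeatureRecord],
                         orf_seqs_self: Mapping[str, str],
                         orf_seqs_other: Mapping[str, str],
                         other_chromosomes: Mapping[str, str] | None = None,
                         min_cov: float = 0.5, min_id: float = 0.95,
                         k: int = 13) -> UniqueGeneReport:
    """Align each candidate ORF to the other genome's ORF set and classify.

    A qualifying match covers at least ``min_cov`` of the candidate at
    ``min_id`` identity or better. Candidates with a qualifying match on
    their own chromosome (per ``other_chromosomes``) are flagged for
    manual inspection rather than silently excluded.
    """
    names = []
    for f in candidates:
        n = _norm_name(f.gene_name)
        if n not in orf_seqs_self:
            raise ValueError(f"candidate {f.gene_name!r} has no ORF sequence")
        names.append(n)
    if not names:
        return UniqueGeneReport([], {}, {}, [], min_cov, min_id)

    target = Genome.from_records(
        [SequenceRecord(n, s) for n, s in orf_seqs_other.items()],
        name="other_orfs")
    query = Genome.from_records(
        [SequenceRecord(n, orf_seqs_self[n]) for n in dict.fromkeys(names)],
        name="candidates")
    blocks = align_contigs(query, target, k=k, min_chain_anchors=2)

    qualifying: dict[str, list[tuple[str, float, float]]] = {}
    diverged: dict[str, list[tuple[str, float, float]]] = {}
    for b in blocks:
        cov = b.qspan / b.qlen
        if cov < min_cov:
            continue
        entry = (b.tid, b.identity, cov)
        if b.identity >= min_id:
            qualifying.setdefault(b.qid, []).append(entry)
        else:
            diverged.setdefault(b.qid, []).append(entry)

    truly_absent = [n for n in dict.fromkeys(names)
                    if n not in qualifying and n not in diverged]
    inspect = []
    if other_chromosomes is not None:
        cand_chrom = {_norm_name(f.gene_name): f.seqid for f in candidates}
        for n, hits in qualifying.items():
            for tid, _ident, _cov in hits:
                if other_chromosomes.get(tid) == cand_chrom.get(n):
                    inspect.append(n)
                    break
    return UniqueGeneReport(
        truly_absent=truly_absent, homologue_map=qualifying,
        diverged_matches=diverged, inspect_same_chromosome=sorted(inspect),
        min_cov=min_cov, min_id=min_id)


@dataclass
class RepeatCensus:
    """Non-redundant locations of dispersed repeat families."""

    #: family -> list of (seqid, start, end, best identity)
    locations: dict[str, list[tuple[str, int, int, float]]]

    @property
    def totals(self) -> dict[str, int]:
        return {fam: len(locs) for fam, locs in self.locations.items()}

    @property
    def total(self) -> int:
        return sum(self.totals.values())


def census_repeat_family(genome: Genome, family_probes: Sequence[SequenceRecord],
                         min_align: int = 2_000, min_identity: float = 0.9,
                         k: int = 15) -> RepeatCensus:
    """Count dispersed repeat elements per family by probe alignment.

    Each probe's id names its family. Alignments spanning at least
    ``min_align`` bp of the genome at ``min_identity`` or better are kept;
    overlapping locations of the same family are merged into one
    non-redundant location whose identity is the best of its constituents.
    """
    if not family_probes:
        raise ValueError("empty repeat probe set")
    query = Genome.from_records(list(family_probes), name="probes")
    blocks = align_contigs(query, genome, k=k)
    per_family: dict[str, list[tuple[str, int, int, float]]] = {}
    for b in blocks:
        if b.tspan < min_align or b.identity < min_identity:
            continue
        per_family.setdefault(b.qid, []).append(
            (b.tid, b.tstart, b.tend, b.identity))
    merged: dict[str, list[tuple[str, int, int, float]]] = {}
    for fam, locs in per_family.items():
        locs.sort()
        out: list[tuple[str, int, int, float]] = []
        for sid, s, e, ident in locs:
            if out and out[-1][0] == sid and s <= out[-1][2]:
                psid, ps, pe, pid = out[-1]
                out[-1] = (psid, ps, max(pe, e), max(pid, ident))
            else:
                out.append((sid, s, e, ident))
        merged[fam] = out
    return RepeatCensus(locations=merged)


def panel_attribution(orf: SequenceRecord, panel: Sequence[Genome],
                      min_cov: float = 0.5, k: int = 13,
                      identity_decimals: int = 4,
                      ) -> list[tuple[str, float]]:
    """Rank panel strains by their best alignment to one ORF.

    For each strain only the best alignment is counted (highest identity,
    ties broken by longest aligned span then position); alignments covering
    less than ``min_cov`` of the ORF are ignored. The result is sorted by
    descending identity (rounded to ``identity_decimals`` so that equally
    good strains tie), then by strain name; strains without a qualifying
    alignment are absent.
    """
    if not panel:
        raise ValueError("empty strain panel")
    results: list[tuple[str, float]] = []
    for strain in panel:
        if not strain.name:
            raise ValueError("every panel genome needs a name")
        blocks = align_contigs(Genome([(orf, False)]), strain, k=k,
                               min_chain_anchors=2)
        best = None
        for b in blocks:
            if b.qspan / b.qlen < min_cov:
                continue
            key = (round(b.identity, identity_decimals), b.qspan,
                   -b.tstart)
            if best is None or key > best[0]:
                best = (key, b)
        if best is not None:
            results.append((strain.name, best[0][0]))
    results.sort(key=lambda x: (-x[1], x[0]))
    return results
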