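"""Synthetic genomes, population mixtures, long reads and fragmented
assemblies with full planted ground truth.

The generator emulates the structure of a small budding-yeast-like genome:

* multi-chromosome genomes whose chromosomes carry terminal telomere
  repeat arrays and interspersed ~6 Kbp dispersed repeat elements
  (retrotransposon-like, drawn from family consensus sequences with
  per-copy divergence);
* an optional repeat-mediated reciprocal translocation between two
  designated chromosomes, present in a configurable fraction of the
  simulated cell population, with unique single-copy genes planted
  immediately flanking the mediating repeats;
* circular replicons (mitochondrial-genome/plasmid analogues) whose linear
  contig representation carries a duplicated terminal overlap;
* long reads with a truncated log-normal length distribution and a
  per-base mismatch/insertion/deletion error model;
* a fragmented "short-read-like" assembly that breaks at every repeat
  element, never assembles telomere arrays, and omits a configurable
  amount of subtelomeric sequence.

Every stochastic choice flows from one integer seed, so a fixed
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_formats import (FeatureRecord, Genome, IntervalSet, SequenceRecord,
                         revcomp)

__all__ = [
    "SimConfig",
    "SimTruth",
    "ReadOrigin",
    "FragmentTruth",
    "simulate_genome",
    "apply_translocation",
    "simulate_reads",
    "fragment_assembly",
    "mutate_sequence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one simulation scenario.

    Defaults model the sequencing conditions this pipeline is designed
    for: ~10 Kbp mean read length, ~10% total error split over
    mismatch/insertion/deletion, ~6 Kbp dispersed repeats, 50x coverage.
    """

    n_chromosomes: int = 12
    chromosome_length_range: tuple[int, int] = (80_000, 130_000)
    telomere_unit: str = "TGTGGGTGTGGT"
    telomere_array_length: int = 1_500
    #: per-chromosome (left, right) telomere presence; None = all present
    telomere_pattern: list[tuple[bool, bool]] | None = None
    n_repeat_elements: int = 20
    repeat_length_mean: int = 6_000
    repeat_length_sd: int = 400
    repeat_families: int = 2
    repeat_divergence: float = 0.03
    n_genes: int = 150
    gene_length_range: tuple[int, int] = (1_000, 3_000)
    n_subtel_genes_per_end: int = 1
    #: (length, terminal duplication length) per circular replicon
    circular_replicons: list[tuple[int, int]] = field(default_factory=list)
    #: chromosome index pair carrying the designated translocation repeats
    translocation: tuple[int, int] | None = None
    #: distance between a designated repeat and its flanking unique genes
    flank_gene_gap: int = 300
    mixture_fraction: float = 0.0
    read_coverage: float = 50.0
    read_length_mean: float = 10_000.0
    read_length_sigma: float = 0.55
    read_length_bounds: tuple[int, int] = (500, 60_000)
    #: per-base (mismatch, insertion, deletion) rates
    error_rates: tuple[float, float, float] = (0.04, 0.03, 0.03)
    #: fragmented-assembly controls
    omit_total_bp: int = 20_000
    omit_window: int = 5_000
    keep_small_contigs: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        for r in self.error_rates:
            if not 0 <= r <= 1:
                raise ValueError("error rates must lie in [0, 1]")
        if not 0 <= self.mixture_fraction <= 1:
            raise ValueError("mixture_fraction must lie in [0, 1]")
        if self.translocation is not None:
            a, b = self.translocation
            if a == b or not (0 <= a < self.n_chromosomes) \
                    or not (0 <= b < self.n_chromosomes):
                raise ValueError("translocation needs two distinct valid "
                                 "chromosome indices")


@dataclass
class ReadOrigin:
    """Planted origin of one simulated read."""

    read_id: str
    architecture: str
    replicon: str
    start: int
    end: int
    strand: str


@dataclass
class SimTruth:
    """Planted ground truth of a simulated genome."""

    config: SimConfig
    genome: Genome
    annotations: list[FeatureRecord]
    #: per chromosome: list of telomere-array intervals (0, 1 or 2)
    telomeres: dict[str, list[tuple[int, int]]]
    repeat_elements: list[FeatureRecord]
    #: terminal duplication [0, d) recorded per circular replicon id
    circular_duplications: dict[str, int]
    # translocation bookkeeping (None when not configured)
    chrA: str | None = None
    chrB: str | None = None
    repeatA: tuple[int, int] | None = None
    repeatB: tuple[int, int] | None = None
    flank_genes: dict[str, str] = field(default_factory=dict)
    cutA: int | None = None
    cutB: int | None = None
    translocated_genome: Genome | None = None
    translocated_annotations: list[FeatureRecord] | None = None


@dataclass
class FragmentTruth:
    """Ground truth of a fragmented short-read-like assembly."""

    #: contig id -> (source seqid, start, end) on the parent genome
    contig_sources: dict[str, tuple[str, int, int]]
    #: deliberately dropped outer chromosome windows (the planted omissions)
    planted_windows: IntervalSet
    #: everything absent from the emitted contigs (complement of sources)
    omitted: IntervalSet

    def omitted_with_small_contigs(self, min_contig: int,
                                   ) -> IntervalSet:
        """Genome coordinates not represented by any contig of at least
        ``min_contig`` bp — the expected gained set of a comparison that
        applies the same contig length filter."""
        out = IntervalSet()
        for seqid, ivs in self.omitted.items():
            for s, e in ivs:
                out.add(seqid, s, e)
        for cid, (seqid, s, e) in self.contig_sources.items():
            if e - s < min_contig:
                out.add(seqid, s, e)
        return out


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def mutate_sequence(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitution-only divergence: each base replaced by a different base
    with probability ``divergence``."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    vals = np.zeros(len(arr), dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        vals[arr == b] = i
    hit = rng.random(len(arr)) < divergence
    vals[hit] = (vals[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
    return _BASES[vals].tobytes().decode("ascii")


def _tandem_array(unit: str, length: int) -> str:
    reps = length // len(unit) + 1
    return (unit * reps)[:length]


def _place(rng: np.random.Generator, occupied: list[tuple[int, int]],
           length: int, lo: int, hi: int, margin: int = 200,
           tries: int = 2000) -> int:
    """Random start in [lo, hi - length] clear of occupied intervals."""
    if hi - lo < length:
        raise ValueError("infeasible placement: feature exceeds available span")
    for _ in range(tries):
        s = int(rng.integers(lo, hi - length + 1))
        e = s + length
        if all(e + margin <= os or s >= oe + margin for os, oe in occupied):
            occupied.append((s, e))
            return s
    raise ValueError("infeasible placement: no free position found")


def simulate_genome(config: SimConfig) -> tuple[Genome, list[FeatureRecord], SimTruth]:
    """Generate a genome, its annotations and the planted truth.

    Chromosomes carry telomere arrays at both ends (unless masked by
    ``telomere_pattern``); repeat elements are placed away from genes; when
    a translocation is configured, one designated repeat per chromosome of
    the pair is planted with unique flanking genes immediately beside it;
    circular replicons are emitted with a recorded terminal duplication.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_chromosomes
    if config.telomere_pattern is not None and len(config.telomere_pattern) != n:
        raise ValueError("telomere_pattern length must equal n_chromosomes")

    lo, hi = config.chromosome_length_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n)]
    names = [f"chr{i + 1:02d}" for i in range(n)]
    seqs = [_random_seq(rng, L) for L in lengths]

    tel = config.telomere_array_length
    telomeres: dict[str, list[tuple[int, int]]] = {}
    for i, name in enumerate(names):
        left, right = (config.telomere_pattern[i]
                       if config.telomere_pattern is not None else (True, True))
        array = _tandem_array(config.telomere_unit, tel)
        ivs = []
        s = seqs[i]
        if left:
            s = array + s[tel:]
            ivs.append((0, tel))
        if right:
            s = s[:len(s) - tel] + array
            ivs.append((len(s) - tel, len(s)))
        seqs[i] = s
        telomeres[name] = ivs

    occupied: list[list[tuple[int, int]]] = [
        [(0, tel), (lengths[i] - tel, lengths[i])] for i in range(n)]

    annotations: list[FeatureRecord] = []
    repeat_elements: list[FeatureRecord] = []
    consensi = [_random_seq(rng, config.repeat_length_mean)
                for _ in range(config.repeat_families)]
    family_names = [f"TyF{j + 1}" for j in range(config.repeat_families)]

    gene_counter = 0

    def _plant_gene(chrom: int, start: int, length: int, name: str | None = None
                    ) -> FeatureRecord:
        nonlocal gene_counter
        gene_counter += 1
        gname = name or f"GENE{gene_counter:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        feat = FeatureRecord(seqid=names[chrom], start=start,
                             end=start + length, strand=strand, type="gene",
                             gene_name=gname, feature_id=f"g{gene_counter:04d}")
        annotations.append(feat)
        return feat

    def _plant_repeat(chrom: int, start: int, length: int, family: int
                      ) -> FeatureRecord:
        copy = mutate_sequence(consensi[family][:length],
                               config.repeat_divergence, rng)
        if length > len(copy):
            copy = copy + _random_seq(rng, length - len(copy))
        seqs[chrom] = (seqs[chrom][:start] + copy
                       + seqs[chrom][start + length:])
        feat = FeatureRecord(seqid=names[chrom], start=start,
                             end=start + length, strand="+",
                             type="dispersed_repeat",
                             gene_name=family_names[family],
                             feature_id=f"rep{len(repeat_elements) + 1:03d}")
        repeat_elements.append(feat)
        annotations.append(feat)
        return feat

    truth = SimTruth(config=config, genome=Genome(), annotations=annotations,
                     telomeres=telomeres, repeat_elements=repeat_elements,
                     circular_duplications={})

    # designated translocation repeats with adjacent unique flanking genes:
    #   flank_left | gap | repeat | gap | flank_right
    if config.translocation is not None:
        ia, ib = config.translocation
        gap = config.flank_gene_gap
        glen = config.gene_length_range[0]
        for which, chrom, frac in (("A", ia, 0.6), ("B", ib, 0.4)):
            rep_len = config.repeat_length_mean
            span = glen + gap + rep_len + gap + glen
            center = int(lengths[chrom] * frac)
            start = _place(rng, occupied[chrom], span,
                           max(tel + 2_000, center - span),
                           min(lengths[chrom] - tel - 2_000, center + span))
            gl = _plant_gene(chrom, start, glen)
            rep = _plant_repeat(chrom, start + glen + gap, rep_len, family=0)
            gr = _plant_gene(chrom, start + glen + gap + rep_len + gap, glen)
            if which == "A":
                truth.chrA = names[chrom]
                truth.repeatA = (rep.start, rep.end)
                truth.flank_genes["A_left"] = gl.gene_name
                truth.flank_genes["A_right"] = gr.gene_name
            else:
                truth.chrB = names[chrom]
                truth.repeatB = (rep.start, rep.end)
                truth.flank_genes["B_left"] = gl.gene_name
                truth.flank_genes["B_right"] = gr.gene_name

    # interspersed repeat elements, away from telomeres and planted features
    total_len = sum(lengths)
    weights = np.array(lengths, dtype=float) / total_len

    def _place_on_some_chromosome(length: int, lo_margin: int, hi_margin: int,
                                  ) -> tuple[int, int]:
        """Try a length-weighted random chromosome first, then the rest."""
        first = int(rng.choice(n, p=weights))
        for chrom in [first] + [c for c in rng.permutation(n) if c != first]:
            try:
                start = _place(rng, occupied[chrom], length,
                               tel + lo_margin,
                               lengths[chrom] - tel - hi_margin)
                return int(chrom), start
            except ValueError:
                continue
        raise ValueError("infeasible placement: no free position found on "
                         "any chromosome")

    for _ in range(config.n_repeat_elements):
        length = int(np.clip(rng.normal(config.repeat_length_mean,
                                        config.repeat_length_sd),
                             2_500, 2 * config.repeat_length_mean))
        family = int(rng.integers(0, config.repeat_families))
        chrom, start = _place_on_some_chromosome(length, 12_000, 12_000)
        _plant_repeat(chrom, start, length, family)

    # subtelomeric genes inside the outer windows (niche-adaptation analogue)
    for chrom in range(n):
        glen = int(rng.integers(*config.gene_length_range))
        for left in (True, False):
            for _ in range(config.n_subtel_genes_per_end):
                if left:
                    s = _place(rng, occupied[chrom], glen, tel + 200,
                               tel + 4_000 + glen)
                else:
                    s = _place(rng, occupied[chrom], glen,
                               lengths[chrom] - tel - 4_000 - glen,
                               lengths[chrom] - tel - 200)
                _plant_gene(chrom, s, glen)

    # bulk gene content
    for _ in range(config.n_genes):
        glen = int(rng.integers(*config.gene_length_range))
        chrom, start = _place_on_some_chromosome(glen, 500, 500)
        _plant_gene(chrom, start, glen)

    replicons: list[tuple[SequenceRecord, bool]] = [
        (SequenceRecord(names[i], seqs[i]), False) for i in range(n)]

    for j, (clen, dup) in enumerate(config.circular_replicons):
        if dup >= clen:
            raise ValueError("terminal duplication must be shorter than the "
                             "circular replicon")
        circ = _random_seq(rng, clen)
        cid = f"circ{j + 1:02d}"
        replicons.append((SequenceRecord(cid, circ + circ[:dup]), True))
        truth.circular_duplications[cid] = dup

    genome = Genome(replicons, name="simulated")
    truth.genome = genome
    annotations.sort(key=lambda f: (f.seqid, f.start))
    return genome, annotations, truth


def apply_translocation(genome: Genome, truth: SimTruth
                        ) -> tuple[Genome, SimTruth]:
    """Reciprocal exchange of chromosome arms at the designated repeats.

    Both chromosomes are cut at the same offset inside their designated
    repeat element (emulating homologous recombination between the repeat
    copies); chromosome count and total genome length are preserved. When
    no translocation is configured, the genome is returned unchanged.
    """
    if truth.config.translocation is None:
        return genome, truth
    if truth.repeatA is None or truth.repeatB is None:
        raise ValueError("translocation requested but no designated repeat "
                         "pair was planted")
    a, b = truth.chrA, truth.chrB
    sa, sb = genome[a].sequence, genome[b].sequence
    lenRA = truth.repeatA[1] - truth.repeatA[0]
    lenRB = truth.repeatB[1] - truth.repeatB[0]
    off = min(lenRA, lenRB) // 2
    cutA = truth.repeatA[0] + off
    cutB = truth.repeatB[0] + off
    var_ab = SequenceRecord(f"{a}-{b}", sa[:cutA] + sb[cutB:])
    var_ba = SequenceRecord(f"{b}-{a}", sb[:cutB] + sa[cutA:])
    replicons = []
    for rec, circ in genome:
        if rec.id == a:
            replicons.append((var_ab, False))
        elif rec.id == b:
            replicons.append((var_ba, False))
        else:
            replicons.append((rec, circ))
    variant = Genome(replicons, name="translocated")

    def _remap(f: FeatureRecord) -> FeatureRecord:
        if f.seqid == a:
            if f.end <= cutA:
                return replace(f, seqid=var_ab.id)
            return replace(f, seqid=var_ba.id,
                           start=f.start - cutA + cutB, end=f.end - cutA + cutB)
        if f.seqid == b:
            if f.end <= cutB:
                return replace(f, seqid=var_ba.id)
            return replace(f, seqid=var_ab.id,
                           start=f.start - cutB + cutA, end=f.end - cutB + cutA)
        return f

    var_annot = [_remap(f) for f in truth.annotations
                 if not (f.seqid in (a, b) and f.start < (cutA if f.seqid == a else cutB) < f.end)]
    new_truth = replace(truth, cutA=cutA, cutB=cutB,
                        translocated_genome=variant,
                        translocated_annotations=var_annot)
    return variant, new_truth


def _inject_errors(seq: str, rates: tuple[float, float, float],
                   rng: np.random.Generator) -> str:
    """Inject mismatch/insertion/deletion errors, vectorised.

    Rates are interpreted per alignment column — the same denominator a
    CIGAR-based error-rate estimate uses — so a configured total of 0.10
    plants a generating alignment whose column error rate is 0.10. Since
    insertions add columns beyond the template length, the per-template-base
    probabilities are scaled up by 1/(1 - p_ins) to keep the per-column
    rate at its nominal value.
    """
    p_mis, p_ins, p_del = (r / (1.0 - rates[1]) for r in rates)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    vals = np.zeros(len(arr), dtype=np.int64)
    for i, bch in enumerate(b"ACGT"):
        vals[arr == bch] = i
    u = rng.random(len(vals))
    dele = u < p_del
    mis = (u >= p_del) & (u < p_del + p_mis)
    vals = vals.copy()
    vals[mis] = (vals[mis] + rng.integers(1, 4, int(mis.sum()))) % 4
    kept = vals[~dele]
    n_ins = rng.binomial(len(vals), p_ins)
    if n_ins:
        pos = rng.integers(0, len(kept) + 1, n_ins)
        kept = np.insert(kept, np.sort(pos), rng.integers(0, 4, n_ins))
    return _BASES[kept].tobytes().decode("ascii")


def simulate_reads(architectures: Sequence[tuple[Genome, float]],
                   config: SimConfig,
                   n_reads: int | None = None,
                   ) -> tuple[list[SequenceRecord], list[ReadOrigin]]:
    """Simulate long reads from a weighted mixture of genome architectures.

    Read lengths follow a log-normal distribution (mean
    ``config.read_length_mean``) truncated to ``read_length_bounds``; each
    read's architecture is drawn with the given weights (which must sum
    to 1), its replicon proportionally to replicon length, and errors are
    injected per the (mismatch, insertion, deletion) model. Reads from the
    minus strand are emitted reverse-complemented. Origins carry the exact
    source interval of every read.
    """
    weights = np.array([w for _, w in architectures], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"architecture weights must sum to 1, got {weights.sum()}")
    names = []
    for g, _ in architectures:
        if not g.name:
            raise ValueError("each architecture Genome needs a name")
        names.append(g.name)
    if len(set(names)) != len(names):
        raise ValueError("architecture names must be distinct")

    rng = np.random.default_rng(config.seed + 1)
    mean, sigma = config.read_length_mean, config.read_length_sigma
    mu = np.log(mean) - sigma ** 2 / 2
    if n_reads is None:
        n_reads = int(round(config.read_coverage
                            * architectures[0][0].total_length() / mean))

    lo, hi = config.read_length_bounds
    reads: list[SequenceRecord] = []
    origins: list[ReadOrigin] = []
    arch_idx = rng.choice(len(architectures), size=n_reads, p=weights)
    lens = np.clip(rng.lognormal(mu, sigma, size=n_reads), lo, hi).astype(int)
    for i in range(n_reads):
        genome, _ = architectures[arch_idx[i]]
        repl_lengths = np.array([len(r) for r, _ in genome], dtype=float)
        ridx = int(rng.choice(len(genome.replicons),
                              p=repl_lengths / repl_lengths.sum()))
        rec, _ = genome.replicons[ridx]
        L = min(int(lens[i]), len(rec))
        start = int(rng.integers(0, len(rec) - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = rec.sequence[start:start + L]
        frag = _inject_errors(frag, config.error_rates, rng)
        if strand == "-":
            frag = revcomp(frag)
        rid = f"read{i + 1:06d}"
        reads.append(SequenceRecord(rid, frag))
        origins.append(ReadOrigin(rid, names[arch_idx[i]], rec.id,
                                  start, start + L, strand))
    return reads, origins


def fragment_assembly(genome: Genome, annotations: list[FeatureRecord],
                      truth: SimTruth, config: SimConfig | None = None,
                      ) -> tuple[Genome, FragmentTruth]:
    """Emulate a short-read assembly of ``genome``: break at every repeat
    element, drop telomere arrays and circular replicons, and omit
    ``omit_total_bp`` of subtelomeric sequence in ``omit_window``-sized
    outer chromosome windows chosen at random.

    Contigs shorter than 1 Kbp are retained when ``keep_small_contigs`` so
    that downstream contig-length filters have something to reject. The
    returned :class:`FragmentTruth` records every omitted interval.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 2)

    chrom_ids = [rec.id for rec, circ in genome if not circ]
    lengths = genome.lengths()

    # choose chromosome ends for the planted subtelomeric omissions
    n_windows = config.omit_total_bp // config.omit_window if config.omit_window else 0
    ends = [(cid, side) for cid in chrom_ids for side in ("L", "R")]
    planted = IntervalSet()
    if n_windows > len(ends):
        raise ValueError("omit_total_bp requires more chromosome ends than exist")
    if n_windows:
        chosen = rng.choice(len(ends), size=n_windows, replace=False)
        for j in sorted(chosen):
            cid, side = ends[j]
            w = config.omit_window
            if side == "L":
                planted.add(cid, 0, w)
            else:
                planted.add(cid, lengths[cid] - w, lengths[cid])

    removed = IntervalSet()
    for seqid, ivs in planted.items():
        for s, e in ivs:
            removed.add(seqid, s, e)
    for cid, ivs in truth.telomeres.items():
        for s, e in ivs:
            removed.add(cid, s, e)
    for rep in truth.repeat_elements:
        removed.add(rep.seqid, rep.start, rep.end)

    contigs: list[SequenceRecord] = []
    sources: dict[str, tuple[str, int, int]] = {}
    counter = 0
    for rec, circ in genome:
        if circ:
            continue  # circular replicons stay unassembled (mitochondrion-like)
        kept = IntervalSet({rec.id: removed.intervals(rec.id)}).complement(
            {rec.id: len(rec)})
        for s, e in kept.intervals(rec.id):
            if e - s < 1_000 and not config.keep_small_contigs:
                continue
            counter += 1
            cid = f"ctg{counter:04d}"
            contigs.append(SequenceRecord(cid, rec.sequence[s:e]))
            sources[cid] = (rec.id, s, e)

    covered = IntervalSet()
    for cid, (seqid, s, e) in sources.items():
        covered.add(seqid, s, e)
    omitted = covered.complement({cid: lengths[cid] for cid in chrom_ids})
    for rec, circ in genome:
        if circ:
            omitted.add(rec.id, 0, len(rec))

    frag = Genome([(c, False) for c in contigs], name="fragmented")
    return frag, FragmentTruth(contig_sources=sources,
                               planted_windows=planted, omitted=omitted)
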