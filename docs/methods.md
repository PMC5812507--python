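# Methods

`nanocurate` re-implements, as tested library code, the analysis steps a
long-read microbial genome assembly project performs after the assembler
has run: curating assembler artifacts, quantifying what a long-read
assembly adds over a fragmented short-read assembly, comparing gene
content between two annotated genomes, and diagnosing chromosome-structure
heterogeneity in the sequenced population from junction-spanning reads.
Everything is exercised end-to-end on synthetic genomes with planted
ground truth; this note records the models, the defaults and their
rationale, and what the synthetic scenarios do and do not demonstrate.

## Coordinate conventions

All internal coordinates are 0-based half-open. GFF3 and the
`show-coords`-style TSV are 1-based inclusive on disk and converted
exactly once, at the I/O boundary (`io_formats`); PAF and BED pass
through unchanged. Sequences are `{A,C,G,T,N}`; lower-case input is
upper-cased on read, and `N` (emitted by gap joins) is never counted as a
match by the aligner.

## The internal aligner

The package carries its own anchor-and-chain aligner rather than wrapping
an external tool, so that every test and every simulated scenario is
self-contained; pre-computed PAF or coords files from any external
aligner can be imported instead when working with real data.

1. **Anchors.** Exact k-mer matches (default k = 15) on both strands,
   found through a sorted-array index over the target. k-mers occurring
   more than `max_occ` = 100 times in the target are skipped — this is a
   repeat-saturation guard, and it means tandem arrays (telomere repeats)
   produce no anchors by themselves.
2. **Chains.** Anchors grouped by (target replicon, strand) are clustered
   by diagonal with tolerance `max_gap` (default 500 bp, the maximum
   indel drift tolerated inside one alignment), then scanned in query
   order; a gap larger than `max_gap` on either axis or a
   target-coordinate reversal closes the chain. Chains with fewer than
   `min_chain_anchors` = 3 anchors are dropped.
3. **Closure.** Each chain's query/target span is globally aligned
   (edlib) to produce an extended CIGAR distinguishing `=` from `X`;
   `block_len` counts alignment columns *including indels*, so
   `identity = matches / block_len` is deliberately conservative.
4. **Extension.** Each block is extended up to 2 kb beyond its outermost
   anchors by score-trimmed alignment of the flanks (+1 match, −2
   mismatch/indel, cut at the running-score maximum). This recovers
   homologous flanking sequence whose k-mers are too repetitive to anchor
   — in particular telomere arrays adjacent to unique sequence — while
   stopping quickly in non-homologous sequence.

Read mapping (`map_read`) reuses the same chains: the best chain is
closed with base-level alignment, unanchored read termini become soft
clips, and mapping quality is a deliberate two-level proxy — 60 when the
best chain's anchor count exceeds the best rival placement by more than
5%, else 0. The downstream consumer only ever thresholds at "mapq ≥ 1",
so a calibrated scale would add nothing.

One-to-one filtering (`filter_one_to_one`) visits blocks by descending
(matches, block_len) with lexicographic tie-breaks and keeps a block iff
it overlaps nothing already kept by more than 50 bp on either axis. This
greedy rule is deterministic; tests verify it against an independent
pairwise restatement on random instances. Breakpoint detection passes a
repeat-scale tolerance (10 kb) instead, because at a repeat-mediated
junction both chimeric arms legitimately align through the homologous
repeat copy.

The aligner's identity estimates are cross-checked against minimap2 on a
rearranged toy sequence in the test suite; minimap2 is never used as the
implementation. The aligner makes no claim of replicating any external
tool's parameter set.

## Error-rate estimation

`cigar_error_rate` pools (X + I + D) / (= + X + I + D) over reads passing
the mapq ≥ 1 and ≤ 500 nt terminal-clipping gates (the clipping gate
protects against partial, repeat-induced placements). The estimator
requires extended CIGARs and refuses plain `M`.

The simulator's error rates are interpreted **per alignment column**, the
same denominator the estimator uses: since insertions add columns beyond
the template, per-template-base probabilities are scaled by 1/(1 − p_ins)
so a configured 10% plants a generating alignment whose column error rate
is 10%. The residual gap between planted and estimated rates is then the
parsimony of optimal alignment (an optimal path can explain random edits
with slightly fewer operations), empirically ≈ 2–5% relative — inside the
±1 percentage-point recovery target at all tested rates (2%, 10%, 13%).

## Synthetic genomes

`SimConfig` defaults describe the study conditions: 12 chromosomes of
80–130 kb (≈ 1.2 Mb total — a scaled-down yeast-like genome that keeps
every scenario inside minutes on one CPU), telomere arrays of a fixed
12-mer unit (1.5 kb per end), ~6 kb dispersed repeat elements drawn from
family consensus sequences with 3% per-copy substitution divergence,
genes of 1–3 kb placed clear of repeats (plus one gene per subtelomeric
end, mirroring niche-adaptation gene families), reads with truncated
log-normal lengths (mean 10 kb, bounds 0.5–60 kb), 10% total error split
(0.04, 0.03, 0.03) over mismatch/insertion/deletion, and 50× coverage.
The translocation scenario uses two chromosomes with a designated repeat
on each, flanked immediately by unique genes
(gene–gap–repeat–gap–gene, 300 bp gaps), and an 8 kb mean read length so
that a useful minority of reads spans repeat plus both flanks.

Choices the data do not dictate, decided once:

* **Log-normal read lengths** (σ = 0.55): only means are specified by the
  conditions being emulated; log-normal is the conventional shape for
  nanopore length distributions.
* **Error split** (0.04, 0.03, 0.03): the 10% total has no published
  decomposition; the split is configurable and nothing downstream is
  sensitive to it.
* **3% repeat-copy divergence**: real dispersed repeat families are a few
  percent diverged; ≥ 2% is also what makes architecture classification
  identifiable at all (identical copies would make every junction read
  ambiguous).
* **Quality strings are constant**: no operation in scope consumes base
  qualities.
* **One integer seed** drives every substream; fixed seed ⇒ byte-identical
  FASTA/FASTQ output.

The fragmented "short-read-like" assembly breaks at every repeat element,
never assembles telomere arrays or circular replicons, and omits
`omit_total_bp` (default 20 kb) of outer chromosome windows
(`omit_window` = 5 kb each) at randomly chosen ends — the planted
subtelomeric omissions. Ground truth records every omitted interval, so
the expected "gained" set of a later comparison is exactly the complement
of the ≥ 1 kb contigs' source intervals.

**What the generator does not emulate:** real base-caller error profiles
(homopolymer compression, quality-correlated errors), chimeric reads,
heterozygosity, segmental duplications beyond the planted repeat
families, and rDNA-scale (megabase) repeat arrays. Passing tests
demonstrate the *logic* of each procedure under controlled conditions,
not performance on real flow-cell data.

## Curation

* **Circular-overlap trimming**: prefix vs suffix self-alignment (each
  window = half the contig); a terminal overlap ≥ 1 kb at ≥ 95% identity
  anchored within 50 bp of both contig ends marks the duplicated copy,
  which is cut at the target-side start. The 95% threshold is a design
  default — "nearly identical" has no published number.
* **Repeat-spanning join**: the end of contig A must overlap the start of
  contig B by ≥ 2 kb (≥ 90% identity). With at least one read aligning
  contiguously across the candidate junction and ≥ 100 bp into both
  flanking unique genes, the contigs merge without duplicating the
  overlap; with none, they are concatenated around 500 `N` (gap length is
  a default; none is published). Overlap below the minimum is an error,
  not a silent gap join.
* **Telomere caps**: probes aligned infix-style (full, 3/4 and 1/2
  lengths, both orientations) inside the outer 15 kb windows; a cap needs
  ≥ 50% probe coverage at ≥ 80% identity. Matches closer than 200 bp
  merge (one array, one cap); iterative masking finds duplicated caps.
* **Artifact-tail trimming**: with ≥ 2 caps at one end, the contig is cut
  immediately after the innermost cap when mean read coverage beyond it
  falls below 10% of the contig-wide mean ("little to no coverage"
  quantified; the threshold is exposed). The cap boundary is refined by
  absorbing trailing bases whose 12-mers still occur inside the matched
  cap, so the cut lands on the true array end rather than the probe
  match end.

Every action is logged with coordinates and evidence sufficient to replay
the edit from the original contig.

## Assembly comparison

Contigs ≥ 1 kb of one assembly are aligned to the other
(maxmatch-style, *no* one-to-one filtering by default — multimapped
contigs contribute all their footprints, which collapse per contig);
the complement of the unioned footprint over the target assembly is the
gained (resp. lost) sequence, and genes with ≥ 50% of their span inside
it (boundary ties inclusive) are the gained/lost genes. Organellar and
plasmid replicons can be excluded by id. Gene membership at exactly 50%
is a definition choice; the interval arithmetic is verified against
per-base marking oracles.

## Gene-set comparison

Names are compared as case-insensitive multisets per chromosome
(duplicate-marker suffixes `_dupN`/`_copyN` stripped; unnamed features
never match). Candidate unique ORFs are aligned to the other genome's
full ORF set; a **qualifying homologue** covers ≥ 50% of the query at
≥ 95% identity. A candidate with no detectable cross-alignment at all
(at the coverage gate, any identity) is **truly absent**; one with a
detectable relative below the identity gate is reported separately as a
*diverged match* — present in some form, too divergent to call a
homologue. This three-way split keeps "truly absent" meaning what it
says while preserving the qualifying-match gates. A qualifying match on
the candidate's own chromosome raises a manual-inspection flag rather
than silently excluding the gene.

The repeat-family census keeps probe alignments spanning ≥ 2 kb of the
genome at ≥ 90% identity and merges overlapping locations per family.
The identity gate replaces a database E-value cut-off (the internal
aligner has no database-size null model); with ~3% diverged copies and a
2 kb length floor the two gates select the same elements. Panel
attribution keeps each strain's best alignment (highest identity, ties
by longest span then position) above 50% query coverage and reports
equal-identity strains as ties.

## Translocation analysis

* **Detection**: one-to-one-filtered whole-genome alignment of assembly
  to reference; consecutive blocks (each ≥ 10 kb) of one contig mapping
  to different reference chromosomes define a junction at the facing
  block boundaries; the two junctions of a reciprocal event merge (their
  positions averaged). Because the junction lies inside a near-identical
  repeat, its position is only defined to repeat resolution, and the
  breakpoint is reported with the mediating repeat interval.
* **Dual reference**: all original replicons plus chrA–B and chrB–A
  built at the breakpoint; originals byte-identical.
* **Flanks**: nearest gene outside any repeat location whose name occurs
  exactly once, searched outward from the repeat boundary (≤ 50 kb).
* **Spanning-read classification**: a read supports an architecture iff
  its best alignment is a *single contiguous* alignment on that
  architecture's replicon covering the junction and overlapping both
  flank genes by ≥ 100 bp (no stitching of split alignments — split
  placements are exactly what chimeric molecules produce). Reads whose
  best alignments tie across architectures (within 1% of match count)
  are ambiguous and never assigned; supporters are validated by
  re-alignment against the full dual reference and dropped if their best
  hit moves. For speed, candidate reads are pre-selected by anchor
  chains touching a junction, and base-level alignment is spent only on
  reads whose chains could span; this changes no decisions, only cost.
* **Verdict**: heterogeneous iff ≥ `min_reads` (default 1) validated
  supporters exist on *both* the normal and the translocated side;
  a single supporting molecule is accepted as evidence of a minority
  architecture by default, with ≥ 3 recommended for noisy data.

## Problem sizes and tolerances

The shipped scenarios run on one CPU in a few minutes: gained-sequence
recovery on the 1.2 Mb default genome (±2% of planted truth), circular
trimming exact to the base, error-rate recovery within ±0.01 at 30× over
200 kb, the translocation scenario on a ~300 kb two-chromosome genome at
50× (support ratio within 3 binomial σ of the planted 0.8 mixture; zero
false supporters for a pure population), interval/filter oracle
equivalence on 100 + 100 random instances ≤ 50 kb, and telomere-pattern
recovery on 16 chromosomes. `scripts/acceptance.py` re-runs all of these
from scratch under one seed.

## Known limitations

* The aligner is designed for ≤ tens of Mb of genome on one CPU; it has
  no minimizer subsampling, spaced seeds or SIMD chaining, and is not a
  general-purpose read mapper.
* Breakpoint positions inside long identical repeats are intrinsically
  interval-valued; the reported point coordinate is the block-boundary
  average and should be read together with the repeat interval.
* `classify_spanning_reads` assumes the two architectures differ by one
  reciprocal translocation; nested or multi-junction events are out of
  scope.
* The telomere-cap caller detects arrays resembling the supplied probes;
  heavily degenerate real telomere repeats may need several probes.
* Tandem arrays longer than the 2 kb block extension plus the anchor
  window are not fully attributed to alignment footprints.
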