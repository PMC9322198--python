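# Methods

## Coordinate conventions

All intervals are 0-based half-open (BED). Variant tables are 1-based, as
is conventional for variant formats; a 1-based position *p* lies inside
`[start, end)` iff `start <= p-1 < end`. Chain files follow UCSC
semantics: the "t" side is the source assembly and "q" the target, source
strand is always `+`, and reverse-strand target coordinates count from the
chromosome end. All overlap logic downstream of the liftover is
strandless, so reverse-strand liftover results are reported as
forward-strand intervals.

## Liftover

`map_interval` selects a single best chain among those whose source range
overlaps the query — highest score, ties broken toward the lower chain id —
and walks its ungapped blocks. The mapped fraction is the share of query
bases inside aligned blocks; the result is the *enclosing span* of the
mapped bases in target coordinates, not a split list, because each anchor
is consumed downstream as one interval. An interval maps when the fraction
is `>= min_match` (default 0.5). The published flag this mirrors is a
minimum-match parameter of 0.5; whether the boundary case of exactly 50%
should pass is not decidable from the flag's prose description, so the
tool's conventional `>=` reading is used. Multi-chain union mapping is
deliberately not offered: it would inflate mapped fractions relative to the
classic single-mapping tool behaviour.

`ChainAlignment.invert()` produces the exact inverse mapping. For a
`-`-strand chain this requires reversing block order and reflecting both
sides' coordinates; tests verify that the inverse's per-base map is the
set-theoretic inverse of the forward map.

## Source-side preparation

Anchors are classified promoter / genic / intergenic with promoter windows
of TSS ± 2.5 kb and priority promoter > genic. Only pairs with exactly one
promoter anchor are kept, promoter stored first. Enhancer states: peaks of
the same mark are merged first (abutting peaks count as one region) and
regions shorter than 300 bp are discarded; a state call is *active* when a
qualifying H3K4me1 region and a qualifying H3K27Ac region overlap **each
other** by ≥ 10 bp, *poised* when only H3K4me1 qualifies. The 10 bp
reciprocal-overlap clause is read as mark-to-mark (the alternative,
mark-to-anchor, would make the 1 bp anchor-contact rule redundant);
mark-to-anchor contact is ≥ 1 bp. The merge pre-pass is what makes the
state call invariant to a peak caller fragmenting one region into abutting
pieces. Replicates are pooled; provenance stays in the interaction id.

## Synteny classes and redundancy

Class assignment follows directly from the two liftover outcomes (see
README table). Redundancy among `P_plus_E` records uses a *reciprocal*
"> 50% of each interval" rule on promoters **and** enhancers jointly;
groups are connected components of that relation, with the first member
marked primary. The one-sided reading of "sharing more than 50% of length"
was rejected as non-symmetric. Region annotation priority is promoter >
exonic > intronic > intergenic, with `intragenic` meaning ≥ 1 bp overlap
with any gene span; annotation is strandless because the anchors are
strandless regions. `spans_multiple_genes` is true when a complete third
gene lies inside the promoter–enhancer span or the enhancer is intragenic
to a gene other than the promoter's.

## Concordance scoring

Histone-mark concordance uses a ≥ 50 bp overlap rule against merged
per-tissue layers; the human state is *active* when both marks match,
*unknown* when the tissue lacks an H3K27Ac layer. The cumulative curve
orders tissues by ascending matched count (ties broken by name for
determinism) and reports the running union. TAD status requires full
containment of each anchor — the strictest reading of "located within";
`intra` means one TAD holds both anchors, `inter` that each anchor is in
some TAD but no single TAD holds both. Loop representation is
orientation-free with a ≥ 1 bp anchor-overlap default (no published
threshold exists; it is a config knob), and interactions found in several
datasets count once in the total.

Conservation is summarized per region as the mean per-base score
(uncovered bases score 0); the choice of mean is the simplest defensible
summary where none is prescribed. Shuffled nulls are length- and
chromosome-matched uniform placements; GC matching is not implemented
because the procedure's specification is length/chromosome matching and a
GC constraint is not well defined for a synthetic alphabet. The two-sample
comparison is a two-sided Wilcoxon rank-sum: exact enumeration when both
groups are ≤ 25 and tie-free, otherwise the normal approximation with
continuity and tie corrections; identical constant inputs return the
null-mean statistic with p = 1.

## Disease overlay

Variants are filtered at PPA strictly greater than 0.01. Motif disruption
is a log-odds best-window model: every placement of the motif covering the
variant, both strands, scored as `sum log2((p + 0.01) / 0.25)`; the call is
*lost*/*gained* when the alt-minus-ref best-score delta crosses ±1 bit.
This is a deliberate, transparent stand-in for heavier motif-disruption
scoring models; only the direction calls are consumed downstream. CNV
pathogenicity classes are carried from input, never computed. The
hypergeometric enrichment universe is defined at the CNV level (all CNVs of
both cohorts; successes are CNVs overlapping any remapped anchor) — the
natural exchangeable layout when the published description names only the
test and the cohorts. Degenerate margins (K = 0 or K = N) return p = 1
with a log note. Enhancer-only disruptions keep CNVs hitting an enhancer
but not the promoter of the *same* interaction; `case_exclusive` means no
same-type control CNV reciprocally overlaps (≥ 50%) the case CNV.

## The synthetic world

Each interaction occupies a cassette: 3 kb margin, 2 kb promoter anchor,
8 kb loop gap, 1.5 kb enhancer anchor, 3 kb margin. Cassettes are placed on
two source chromosomes and copied to three target chromosomes in permuted
order with 12 kb spacing plus sub-bin jitter (so planted breakpoints never
share a lattice with the 500 bp conservation bins — without the jitter,
real regions average whole bins while shuffled regions straddle them and
the null rank-sum test becomes conservative). Class fates are realized as
chain structure: `P_plus_E` cassettes are single aligned blocks (30%
inverted to exercise reverse-strand chains), `split` cassettes break
between the anchors onto two target chromosomes, and deletions become `dt`
gaps inside chains rather than absent chains, so partial-overlap fractions
are well defined; a configurable retained fraction (e.g. 0.4, below
minMatch) plants partially-deleted anchors. The generator also records
every anchor's expected target interval by direct arithmetic; tests verify
these against the chain walk, cross-validating two independent code paths.

Default study conditions: 50 interactions (10 per class), 70% active /
30% poised; five tissues with planted match rates 0.80–0.94 (H3K27Ac
layers for three of them), mark coverage ~45% of the enhancer; three TAD
datasets at 0.89/0.87/0.86 intra rates; five loop datasets at 0.21–0.29;
conservation 0.9 (enhancers) vs 0.1 (background), sd 0.03, clipped to
[0, 1]; 95% cCRE overlap; 20% validated-enhancer positives; 70 variants
(30 in-enhancer above the PPA cutoff, 10 below it, 30 outside; 6 planted
motif-losing and 3 motif-gaining); CNV cohorts of 500 + 500 with a planted
odds ratio of 5 over a 0.15 control overlap rate. These mirror the regime
of the motivating neural-stem-cell study at a desk-scale problem size;
rates were chosen once from that study's reported ranges and are exposed as
configuration, not tuned.

With `conservation_signal=False` the track is homogeneous everywhere, so
real and shuffled regions are exchangeable and the rank-sum p-value is
calibrated; with `cnv_odds_ratio=1` the case/control overlap indicators are
i.i.d., making the hypergeometric p-value exactly valid (discrete, hence
super-uniform — null-calibration checks therefore use a one-sided KS test
that rejects only anti-conservative behaviour).

## What the generator does not emulate

Nucleotide composition and chromatin biology are not modelled: sequence is
i.i.d. random apart from planted motif sites, peaks are planted rather than
called from signal, and interaction anchors have uniform sizes. Passing
tests demonstrate that the *computational procedure* is correct and
calibrated under known truth; they say nothing about peak-calling noise,
alignment ambiguity in real chain files, or biological confounding in real
cohorts. Real-data headline counts depend on external resources and are
not reproduced here; the report arithmetic on those published tallies is
checked instead.

## Numerical choices

Hypergeometric tails come from `scipy.stats.hypergeom.sf`. Rank-sum exact
p-values come from `scipy.stats.mannwhitneyu(method="exact")`. The motif
scorer uses the stated pseudocount form without renormalizing rows (the
worked example's closed form fixes this convention). Interval indexes are
per-chromosome interval trees; merged-coverage queries merge hits before
summing so stacked peaks are not double counted. All randomness flows from
`numpy.random.default_rng` seeded by the world seed; derived seeds are
drawn from the parent generator so one integer reproduces the whole world.

## Known limitations

Single-best-chain liftover cannot represent an anchor genuinely split
across two chromosomes inside one mapping (such cases surface as
`below_min_match` instead); redundancy grouping is transitive, so long
overlap chains can join records that do not pairwise overlap; the
pipeline's shuffled null is a single draw per run (seeded) rather than an
averaged ensemble; and `percentage()` rounds for reporting, so partition
identities are checked on counts, never on rounded percentages.
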