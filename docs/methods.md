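# Methods

## Problem setting

Small circular DNA viruses — papillomaviruses (~8 kb double-stranded
circles with seven-plus canonical ORFs) and CRESS-DNA viruses (~1.7–3 kb
single-stranded circles replicating by rolling-circle replication) — are
recovered from metagenomes as linear contigs. Because most assemblers have
no notion of a circular replicon, a circular template is emitted linearized
at an arbitrary point, usually with an identical run of sequence duplicated
at the contig's two ends. `circviro` operates downstream of assembly: it
recognizes that signature, reconstructs the circle, and evaluates the
genome-level evidence (replication-origin stem-loop, ORF complement, size)
that separates plausible viral genomes from fragments.

## Circularity model

A contig of length `n` is called circular when its first `k` and last `k`
characters are exactly equal for some `min_overlap ≤ k ≤ max_overlap_frac·n`;
the largest such `k` is taken and the 5′ copy removed. Matching is exact by
design: the duplication an assembler produces from a circular template is a
literal copy, and tolerating mismatches (a configurable edit-distance slack
exists but defaults to 0) mainly admits false circles. Defaults:
`min_overlap = 10` nt — at 10 nt the chance of an accidental end match on a
random contig is ~4⁻¹⁰ ≈ 10⁻⁶ — and `max_overlap_frac = 0.5`, above which
"contig with duplicated end" stops being the parsimonious reading. An
optional strict mode additionally requires the duplicated end to occur
nowhere else internally, for callers who want tandem artefacts excluded;
it is off by default because true genomes can contain internal repeats.

Long low-complexity dinucleotide runs (the classic failure case is an
extensive `GTGT` tract) are excised *before* end comparison, since a run
abutting the breakpoint masks the terminal repeat. Runs are maximal perfect
tandem repeats with unit length ≤ 2 spanning ≥ 20 nt; 20 nt is our reading
of "extensive" at dinucleotide scale — short enough to catch real tracts,
long enough (4⁻²⁰-scale chance) never to fire on normal sequence.
Overlapping period-1/period-2 candidates are resolved greedily longest-first.

Every circle is reduced to a canonical representative: the
lexicographically least string over all rotations of both strands, computed
with Booth's least-rotation algorithm in O(n). This gives assembler output
that differs only by breakpoint and strand a unique, comparable form.

Contigs with more than 5 % N are reported with a `high_N_skipped` flag
rather than analyzed; sequences are uppercased and U→T on input. GC content
excludes N from numerator and denominator. Coordinates are 0-based
half-open internally; GFF3 output is 1-based inclusive, with wrapped
features split into two parts sharing an ID and `Is_circular=true` on the
region, per the GFF3 convention.

## Stem-loop origin model

The rolling-circle origin is modelled as a conserved nonanucleotide
(canonical `TAGTATTAC`; `max_mismatch = 1` by default, admitting the
common `TAGTATTAA` variant) that must lie inside the loop of a perfect
inverted-repeat hairpin: a 5′ arm that is the exact reverse complement of
the 3′ arm, enclosing a loop that contains the whole nonamer. Among all
qualifying arm pairs the scanner reports the longest arm, breaking ties by
smaller loop and then leftmost position. Defaults `min_arm = 5`,
`max_arm = 20`, `max_loop = 15`, search window ±40 nt bracket the exemplar
geometry (11-bp arms, 11-nt loop) with margin.

This is a deliberate substitution of a combinatorial model for
thermodynamic folding. The canonical origin exemplar is a perfect 11-bp
stem, and a perfect-inverted-repeat criterion is exact, parameter-light and
oracle-testable; wobble pairs, bulges and free-energy ranking are not
modelled (a mismatch-tolerant stem is a configurable extension, default
off). Hairpins weaker than a 5-bp perfect stem will be missed; that is the
price of the model, stated rather than hidden. Both strands are scanned;
a hairpin is strand-symmetric, so minus-strand hits are assessed and
reported in plus-strand coordinates.

## ORF model

ORFs run ATG → first in-frame stop (TAA/TAG/TGA), stop included in the
length, on both strands. Circular genomes are scanned on the doubled
sequence so breakpoint-wrapping frames are found; each ORF is reported once
(start reduced modulo L), capped at one full circle, and nested starts are
suppressed by keeping only the longest ORF per (stop, strand) — the first
ATG after the previous stop. Minus-strand records use coordinates along the
reverse complement; `plus_strand_interval` recovers the plus-strand
footprint. The default threshold is 300 nt including the stop ("larger
than 300 nt" read as ≥ 300 with stop included — a boundary choice), applied
to both genome classes and configurable. A stop-to-stop mode (no ATG
required, getorf-style) exists behind a flag for start-codon-less genes
such as papillomaviral E4; it is off by default. Translation uses the
standard genetic code with one strict rule: any codon containing a
character outside ACGT yields `X` (degenerate codons are *not* resolved
even when unambiguous), keeping protein output deterministic in the
presence of assembly Ns. ORFs are reported positionally; assigning E1/L1
identities would need homology evidence, which is out of scope.

## Identity and demarcation

Percent identity is 100 × matched columns / total alignment columns, so gap
columns count against identity. The definition matters: near the 90 %
type boundary it can shift values a few points relative to gap-excluded
definitions, which is why it is stated here and in the API docs. Alignment
is optimal global with affine gaps via Biopython's `PairwiseAligner`
(nucleotide match +1 / mismatch −2, gap open −10 / extend −1, where "open"
is the score of the first gapped position; BLOSUM62 with the same gap costs
for proteins). Determinism comes from taking the first alignment in the
aligner's canonical order. Protein similarity (reported separately from
identity) counts identical residues plus pairs with positive BLOSUM62
score, over all columns.

The demarcation rule takes the maximum identity of the query L1 over the
reference set, `d = 100 − identity`: `d > 10` new type, `2 ≤ d ≤ 10`
subtype, `d < 2` variant (boundaries follow "more than 10 %" and "less than
2 %" strictly). The functions do not verify that their inputs are L1
genes — that is the caller's responsibility. Sliding-window identity over a
multiple alignment counts a column as identical only when every row agrees,
gaps included as characters; window 400 / step 50 defaults are exposed as
flags since no single choice is canonical, and the final partial window is
reported at its actual width.

## Triage decision table

After normalization, a circle of trimmed length L is categorized:
`papillomavirus_sized` if 6800 ≤ L ≤ 8500 and ≥ 6 ORFs ≥ 300 nt;
else `cress_sized` if it has a stem-loop origin and 1200 ≤ L ≤ 3200;
else `short_circular_defective_or_multicomponent` if it has a stem-loop and
L < 1200 (sub-genome-sized circles retaining replication signals, as seen
for defective molecules and components of multicomponent viruses); else
`circular_unclassified`. Contigs without terminal redundancy are
`not_circular`. The size windows put margins around the magnitudes the
categories describe (~8 kb with seven ORFs; ~1.7–3 kb; ~850 nt) and every
boundary is a config key, because these categories summarize reasoning
about genome architecture, not hard biological constants. The names claim
size and structure only — taxonomy needs homology evidence this package
does not compute.

## Synthetic data

The generator emits what the pipeline assumes: per class, a random i.i.d.
circle at a target GC (0.45 default, between the ~50 % of the genomes that
motivated the windows and typical AT-rich small circles), with features
planted and then *verified recoverable* before the contig is emitted.
Defaults per dataset: 4 papillomavirus-sized circles (7.2–8.2 kb, seven
ORFs), 4 CRESS-sized (1.7–3.0 kb, stem-loop origin + 1–2 ORFs), 6 short
stem-loop circles (700–1000 nt, one ORF), 6 linear contigs (0.5–3 kb);
circular classes carry a 20–60 nt duplicated end at a random breakpoint.

Three hygiene mechanisms make planted truth exact rather than approximate:
planted hairpins get non-pairing flanking bases so the stem cannot extend
by chance; planted ORFs get an in-frame stop immediately upstream so a
background ATG cannot lengthen them; and the background is sterilized — any
chance ORF reaching the caller's threshold is disrupted by writing a stop
codon into it at a position clear of every planted feature, iterating until
the ORF census equals the planted truth (on a random 7.7-kb circle several
such chance ORFs are expected, so this step is load-bearing). A final
verification pass re-runs the scanners and rejects the rare circle that
still disagrees.

Mutation is substitution-dominated (each site substituted with probability
`d`, uniform over the three alternatives — a Jukes–Cantor-style model
chosen because the identities of interest are nucleotide-level); indels
(length 1–3, geometric) are available but default to 0 so realized
divergence is exactly the substitution count. Realized counts are returned
so experiments compare estimates against what actually happened, not the
nominal rate. One root `SeedSequence` spawns per-contig substreams, so
class insertion order never perturbs downstream draws and a single integer
seed reproduces a dataset byte-for-byte. The generator does not simulate
reads, sequencing error, coverage or chimeras: passing its tests shows the
analysis is correct on clean assembler-style output, not that it is robust
to misassembly.

## Problem sizes and numerical notes

The validation suite uses 100 random circles (300–8500 nt) for round-trip
recovery with exhaustive breakpoints on ≤ 60-nt circles, 20 replicates per
divergence level for demarcation recovery on a 1.5-kb gene, 50 random
circles ≤ 2 kb for ORF-oracle equivalence, and all pairs from a batch of 8
strings of length ≤ 7 for alignment-oracle equivalence (exhaustive
enumeration of alignments is feasible only at that scale); these sizes give
each check enough power to catch coordinate and tie-break errors while
keeping the suite fast. Identity values are exact rational arithmetic in
floating point (matches/columns); the only tolerance in the package's own
tests is ±1 percentage point between estimated and realized divergence,
which substitution-only mutants meet with zero error because their optimal
alignments are gapless under the default scoring.

## Known limitations

- Exact-match circularity misses circles whose duplicated ends carry
  sequencing or assembly errors.
- The perfect-stem hairpin model misses thermodynamically stable but
  imperfect stems.
- ORFs are positional; no gene naming, no homology search, no taxonomy.
- No multiple-sequence alignment construction: sliding-window identity
  consumes alignments produced elsewhere.
- The demarcation thresholds are specific to papillomavirus L1; applying
  them to other genes is the caller's decision.
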