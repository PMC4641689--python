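# circviro

Discovery of circular DNA viruses — papillomaviruses and CRESS-DNA
(circular Rep-encoding single-stranded DNA) viruses — from metagenomic
assembly contigs.

Metagenomic assemblers do not assemble circles: a circular template comes
out as a linear contig, typically with an identical stretch of sequence
duplicated at its 3′ and 5′ ends. `circviro` turns such contigs back into
genomes and asks the questions a virus hunter asks of them. It is a library
for people screening assemblies (often from circular-DNA-enriched
sequencing libraries) for small circular viral genomes, with a thin CLI for
pipeline use.

## What it does

- **Circularity detection and trimming** — finds the largest exact
  terminal repeat (first *k* = last *k* nucleotides, `min_overlap ≤ k ≤
  L/2`), excises confounding low-complexity dinucleotide runs (e.g. long
  `GTGT` tracts) first, trims the duplicated end, and produces a canonical
  rotation-and-strand representative so any two assemblies of one circle
  compare equal.
- **Replication-origin scanning** — locates the conserved nonanucleotide of
  rolling-circle replication (canonically `TAGTATTAC`; common variants such
  as `TAGTATTAA` differ at one position) on both strands, wrapping the
  breakpoint, and requires it to sit in the loop of a perfect
  inverted-repeat hairpin (arms exactly reverse-complementary).
- **Circular-aware ORF calling** — six-frame ATG→stop ORF prediction on the
  doubled sequence, so frames crossing the assembly breakpoint are found
  and reported once; nested starts suppressed; optional stop-to-stop mode.
- **Identity and typing** — global affine-gap alignment (match +1,
  mismatch −2, gap open −10, extend −1; BLOSUM62 for proteins), percent
  identity defined as matches over *all* alignment columns (gap columns
  count against identity), all-vs-all identity matrices, sliding-window
  identity along a multiple alignment, and the papillomavirus L1
  demarcation rule: divergence *d* = 100 − identity of the query L1 to its
  closest reference; *d* > 10 % ⇒ new type, 2–10 % ⇒ subtype, *d* < 2 % ⇒
  variant.
- **Triage** — the end-to-end pipeline assigning each contig an
  evidence-based category (papillomavirus-sized, CRESS-sized, short
  defective/multicomponent-sized, circular-unclassified, not-circular).
- **Simulation** — a generator producing contig sets with planted,
  verified-recoverable features (duplicated ends, stem-loop origins,
  breakpoint-wrapping ORFs, controlled point-mutation divergence) plus a
  machine-readable truth table, for validation and benchmarking.

## Worked example

```python
import circviro as cv

exemplar = "CGAGATTCGTCCTTAGTATTAAGACGAATCTCG"   # a published origin context
hit = cv.find_nonamer_sites(exemplar, circular=False)[0]
sl = cv.detect_hairpin(exemplar, hit, circular=False)
print(hit.motif, hit.offset, hit.mismatches, sl.arm_len, sl.loop_len)
```

prints

```
TAGTATTAA 13 1 11 11
```

— the variant nonamer `TAGTATTAA` (one mismatch to canonical `TAGTATTAC`,
at the ninth position) at offset 13, enclosed in a perfect hairpin with
11-bp arms and an 11-nt loop: the textbook CRESS-DNA origin geometry.

Typing a diverged L1 (from `examples/04_identity_typing.py`):

```
query_18%  realized divergence 18.80% -> identity 81.20% -> new_type
```

A query at ~82 % L1 identity to its closest known type falls beyond the
10 % demarcation threshold and is called a new papillomavirus type.

The `examples/` directory has one short script per capability; the CLI
mirrors the library (`circviro simulate | circularize | scan-stemloop |
orfs | identity-matrix | classify-pv | sliding-identity | triage`).

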