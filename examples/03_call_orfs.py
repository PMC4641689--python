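"""Circular-aware ORF calling, including frames that wrap the breakpoint.

A 21-nt toy circle encodes a single ORF only when read across the
breakpoint; a linear reading misses it entirely.
"""

import circviro as cv

toy = "GCCCCCTAAGGGGGGATGCCC"
for circular in (True, False):
    recs = cv.find_orfs(toy, min_len=15, circular=circular)
    mode = "circular" if circular else "linear"
    print(f"{mode:8s}: {len(recs)} ORF(s)")
    for r in recs:
        print(f"          start={r.start} len={r.length_nt} strand={r.strand} "
              f"wraps_breakpoint={r.crosses_breakpoint} protein={r.protein}")
# The ATG at position 15 runs through the breakpoint to the stop at
# position 6 — invisible unless the genome is treated as a circle.

genome = cv.random_circular_genome(7707, gc=0.50, seed=8)
layout = [(200, 900, "+"), (1300, 600, "-"), (2600, 1500, "+"), (6900, 900, "+")]
for i, (start, length, strand) in enumerate(layout):
    genome, _ = cv.plant_orf(genome, start, length, strand, seed=100 + i)
recs = cv.find_orfs(genome, min_len=300)
planted = [r for r in recs if (cv.plus_strand_interval(r, 7707)[0], r.length_nt)
           in {(s, l) for s, l, _ in layout}]
print(f"\n7707-nt genome: recovered {len(planted)}/4 planted ORFs "
      f"(one wraps the breakpoint: {any(r.crosses_breakpoint for r in planted)})")
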