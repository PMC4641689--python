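"""Find the rolling-circle replication origin signature on a CRESS-like circle.

The origin presents a conserved nonanucleotide (canonically TAGTATTAC, often
with a single-base variant) in the loop of a perfect inverted-repeat
hairpin. We scan the published 33-nt origin context, then a full synthetic
genome with a planted origin.
"""

import circviro as cv

exemplar = "CGAGATTCGTCCTTAGTATTAAGACGAATCTCG"
hit = cv.find_nonamer_sites(exemplar, circular=False)[0]
sl = cv.detect_hairpin(exemplar, hit, circular=False)
print(f"nonamer {hit.motif} at offset {hit.offset} "
      f"({hit.mismatches} mismatch to {cv.CANONICAL_NONAMER})")
print(f"hairpin: {sl.arm_len}-bp arms, {sl.loop_len}-nt loop")
# An 11-bp perfect stem around an 11-nt loop holding the nonamer: the
# classic origin geometry of CRESS-DNA viruses.

genome = cv.random_circular_genome(1890, gc=0.45, seed=3)
genome, truth = cv.plant_stemloop(genome, offset=800, arm_len=9, seed=4)
hits = cv.scan_genome(genome)
print(f"\nsynthetic 1890-nt genome: {len(hits)} stem-loop hit(s); "
      f"arm {hits[0].arm_len} bp at offset {hits[0].nonamer.offset} "
      f"(planted at {truth['nonamer_offset']})")
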