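"""Detect and trim assembler terminal redundancy from a circular contig.

A circular template linearized by a metagenomic assembler carries the same
sequence duplicated at its 3' and 5' ends. We build one such contig from a
known 850-nt circle, then recover the circle.
"""

import circviro as cv

circle = cv.random_circular_genome(850, gc=0.45, seed=11)
contig_seq = cv.linearize_with_overlap(circle, breakpoint=321, overlap_len=40)
contig = cv.Contig("contig_1", contig_seq)

overlap = cv.detect_terminal_overlap(contig.seq)
genome = cv.trim_to_circle(contig, overlap)

print(f"contig length          : {contig.length} nt")
print(f"terminal overlap found : {overlap} nt")
print(f"trimmed circle length  : {genome.length} nt (GC {genome.gc:.2%})")
same = cv.canonical_rotation_seq(genome.seq) == cv.canonical_rotation_seq(circle)
print(f"identical to the true circle after canonical rotation: {same}")
# The 40 duplicated nucleotides are the assembler's circularity signature;
# removing them leaves exactly one copy of the 850-nt genome.
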