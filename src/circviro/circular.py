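"""Circularity detection and normalization of assembly contigs.

Metagenomic assemblers linearize a circular template at an arbitrary point
and typically emit the contig with a stretch of identical sequence duplicated
at its 3' and 5' ends (terminal redundancy). This module detects that
signature, trims the duplicated end to recover one full circle, excises
low-complexity dinucleotide runs that confound the end comparison, and
produces a canonical rotation-and-strand representative so that any two
assemblies of the same circle compare equal.
"""

from __future__ import annotations

from Bio.Seq import reverse_complement

from .records import CircularGenome, Contig, LowComplexityRun

VALID_BASES = frozenset("ACGTN")


def clean_seq(seq: str) -> str:
    """Uppercase a raw sequence and map U to T; reject other characters."""
    s = seq.upper().replace("U", "T")
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return s


def detect_terminal_overlap(
    seq: str,
    min_overlap: int = 10,
    max_overlap_frac: float = 0.5,
    max_mismatches: int = 0,
) -> int | None:
    """Length of the assembler's duplicated terminal sequence, if any.

    Returns the largest ``k`` with ``min_overlap <= k <= max_overlap_frac *
    len(seq)`` such that the first ``k`` characters equal the last ``k``
    exactly, or ``None`` if no such ``k`` exists. Matching is exact by
    default — the duplication an assembler leaves on a circular template is
    identical at both ends; ``max_mismatches`` admits that many substitution
    differences for callers working with noisier ends.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if max_overlap_frac > 0.5:
        raise ValueError("max_overlap_frac must be <= 0.5")
    s = clean_seq(seq)
    kmax = int(max_overlap_frac * len(s))
    for k in range(kmax, min_overlap - 1, -1):
        if max_mismatches == 0:
            if s[:k] == s[-k:]:
                return k
        elif sum(a != b for a, b in zip(s[:k], s[-k:])) <= max_mismatches:
            return k
    return None


def overlap_is_unique(seq: str, overlap_len: int) -> bool:
    """Whether the duplicated end occurs nowhere else in the contig.

    Strict-mode companion to :func:`detect_terminal_overlap`: a contig whose
    terminal repeat also occurs internally may be a tandem artefact rather
    than a clean circle.
    """
    s = clean_seq(seq)
    probe = s[:overlap_len]
    first = s.find(probe)
    second = s.find(probe, first + 1)
    return second == len(s) - overlap_len or second == -1


def trim_to_circle(contig: Contig, overlap_len: int) -> CircularGenome:
    """Remove the duplicated 5' end, leaving exactly one full circle."""
    if overlap_len is None or overlap_len < 1:
        raise ValueError("overlap_len must be >= 1 (no overlap means not circular)")
    if overlap_len >= contig.length:
        raise ValueError("overlap_len must be smaller than the contig")
    seq = clean_seq(contig.seq)[overlap_len:]
    return CircularGenome(
        id=contig.id, seq=seq, overlap_len=overlap_len, gc=gc_content(seq)
    )


def find_low_complexity(
    seq: str, max_period: int = 2, min_run: int = 20
) -> list[LowComplexityRun]:
    """All maximal perfect tandem repeats of unit length <= max_period.

    Runs shorter than ``min_run`` are ignored. Overlapping candidates from
    different periods (e.g. a poly-A tail abutting an AT run) are resolved
    greedily in favour of the longer run, longer-first, so the result is
    non-overlapping and sorted by start.
    """
    if max_period not in (1, 2):
        raise ValueError("max_period must be 1 or 2")
    if min_run < 2 * max_period:
        raise ValueError("min_run must be >= 2 * max_period")
    s = clean_seq(seq)
    n = len(s)
    candidates: list[LowComplexityRun] = []
    for period in range(1, max_period + 1):
        i = 0
        while i < n - period:
            j = i + period
            while j < n and s[j] == s[j - period]:
                j += 1
            span = j - i
            if span >= min_run:
                unit = s[i : i + period]
                if period == 1 or unit[0] != unit[1]:
                    candidates.append(LowComplexityRun(i, j, period, unit))
            i = max(i + 1, j - period + 1)
    chosen: list[LowComplexityRun] = []
    for run in sorted(candidates, key=lambda r: (-r.span, r.period, r.start)):
        if all(run.end <= c.start or run.start >= c.end for c in chosen):
            chosen.append(run)
    return sorted(chosen, key=lambda r: r.start)


def truncate_low_complexity(
    contig: Contig, runs: list[LowComplexityRun]
) -> Contig:
    """Excise the given runs from the contig (applied before end trimming)."""
    ordered = sorted(runs, key=lambda r: r.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError("low-complexity intervals overlap")
    seq = contig.seq
    pieces = []
    pos = 0
    for run in ordered:
        pieces.append(seq[pos : run.start])
        pos = run.end
    pieces.append(seq[pos:])
    return Contig(id=contig.id, seq="".join(pieces))


def _least_rotation(s: str) -> int:
    """Index of the lexicographically least rotation (Booth's algorithm)."""
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_rotation_seq(seq: str) -> str:
    """Lexicographically least string over all rotations of both strands.

    Gives every circular sequence a unique representative independent of the
    assembler's breakpoint and of which strand was reported.
    """
    if not seq:
        raise ValueError("empty sequence")
    i = _least_rotation(seq)
    fwd = seq[i:] + seq[:i]
    rc = reverse_complement(seq)
    j = _least_rotation(rc)
    rev = rc[j:] + rc[:j]
    return min(fwd, rev)


def canonical_rotation(genome: CircularGenome) -> CircularGenome:
    """Canonical rotation-and-strand representative of a circular genome."""
    seq = canonical_rotation_seq(genome.seq)
    return CircularGenome(
        id=genome.id,
        seq=seq,
        overlap_len=genome.overlap_len,
        gc=genome.gc,
        truncated_intervals=genome.truncated_intervals,
    )


def gc_content(seq: str) -> float:
    """G+C fraction; N excluded from numerator and denominator."""
    s = clean_seq(seq)
    denom = len(s) - s.count("N")
    if denom == 0:
        raise ValueError("gc_content undefined for an all-N sequence")
    return (s.count("G") + s.count("C")) / denom


def n_fraction(seq: str) -> float:
    s = seq.upper()
    return s.count("N") / len(s) if s else 0.0


def circularize(
    contig: Contig,
    min_overlap: int = 10,
    max_overlap_frac: float = 0.5,
    max_period: int = 2,
    min_run: int = 20,
    strict_unique_ends: bool = False,
) -> CircularGenome | None:
    """Full normalization of one contig: truncate low-complexity runs,
    detect and trim terminal redundancy, and rotate canonically.

    Returns ``None`` when the contig shows no terminal redundancy (i.e. it is
    not recognizably circular) or, in strict mode, when the duplicated end
    also occurs internally.
    """
    cleaned = Contig(contig.id, clean_seq(contig.seq))
    runs = find_low_complexity(cleaned.seq, max_period=max_period, min_run=min_run)
    truncated = truncate_low_complexity(cleaned, runs)
    if truncated.length == 0:
        return None
    overlap = detect_terminal_overlap(
        truncated.seq, min_overlap=min_overlap, max_overlap_frac=max_overlap_frac
    )
    if overlap is None:
        return None
    if strict_unique_ends and not overlap_is_unique(truncated.seq, overlap):
        return None
    genome = trim_to_circle(truncated, overlap)
    genome = CircularGenome(
        id=genome.id,
        seq=genome.seq,
        overlap_len=genome.overlap_len,
        gc=genome.gc,
        truncated_intervals=tuple((r.start, r.end) for r in runs),
    )
    return canonical_rotation(genome)
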