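"""Rolling-circle replication origin scanning.

CRESS-DNA viruses carry a conserved nonanucleotide (canonically TAGTATTAC,
with common single-base variants such as TAGTATTAA) at the origin of
rolling-circle replication, presented in the loop of a stem-loop structure.
This module finds nonamer matches on both strands of a circular genome,
wrapping the assembly breakpoint, and tests whether each sits inside a
perfect inverted-repeat hairpin: two arms that are exact reverse complements
of each other enclosing an unpaired loop that contains the whole nonamer.

The hairpin model is purely combinatorial — no thermodynamics, no wobble
pairs, no bulges. Mismatch tolerance in the stem is deliberately not
modelled by default; the canonical exemplar geometry (an 11-bp perfect stem
around an 11-nt loop) needs none.
"""

from __future__ import annotations

from Bio.Seq import reverse_complement

from .records import NonamerHit, StemLoopHit
from .circular import clean_seq

CANONICAL_NONAMER = "TAGTATTAC"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_nonamer_sites(
    seq: str,
    canonical: str = CANONICAL_NONAMER,
    max_mismatch: int = 1,
    circular: bool = True,
) -> list[NonamerHit]:
    """All nonamer matches within ``max_mismatch`` of the canonical motif.

    Both strands are scanned; on a circular genome the scan wraps the
    breakpoint and each site is reported once. ``offset`` is always the
    plus-strand position of the motif's first base; for minus-strand hits
    ``motif`` is the sequence as read on the minus strand.
    """
    if len(canonical) != 9:
        raise ValueError("canonical motif must be 9 nt")
    if max_mismatch > 3:
        raise ValueError("max_mismatch must be <= 3")
    s = clean_seq(seq)
    L = len(s)
    if L < 9:
        raise ValueError("genome shorter than the nonamer")
    hits: dict[tuple[int, str], NonamerHit] = {}

    def scan(strand_seq: str, strand: str) -> None:
        doubled = strand_seq + strand_seq[:8] if circular else strand_seq
        n_pos = L if circular else L - 8
        for p in range(n_pos):
            word = doubled[p : p + 9]
            if len(word) < 9:
                break
            mm = _hamming(word, canonical)
            if mm <= max_mismatch:
                offset = p if strand == "+" else (L - p - 9) % L
                key = (offset, strand)
                if key not in hits:
                    hits[key] = NonamerHit(word, offset, strand, mm)

    scan(s, "+")
    scan(reverse_complement(s), "-")
    return sorted(hits.values(), key=lambda h: (h.offset, h.strand))


def detect_hairpin(
    seq: str,
    hit: NonamerHit,
    min_arm: int = 5,
    max_arm: int = 20,
    max_loop: int = 15,
    window: int = 40,
    circular: bool = True,
) -> StemLoopHit | None:
    """Best perfect inverted repeat whose loop contains the whole nonamer.

    Among all arm pairs (exact reverse complements) with ``min_arm <= arm <=
    max_arm`` and ``loop_len <= max_loop``, restricted to ±``window`` nt
    around the nonamer, returns the hit with the longest arm; ties broken by
    smaller loop, then leftmost. ``None`` if no qualifying hairpin exists.
    Coordinates in the result are plus-strand circle positions modulo the
    genome length. A hairpin is strand-symmetric, so minus-strand nonamer
    hits are assessed on the same plus-strand context.
    """
    if min(min_arm, max_arm, max_loop, window) <= 0:
        raise ValueError("hairpin parameters must be positive")
    s = clean_seq(seq)
    L = len(s)
    # local context around the nonamer, wrapping the breakpoint if circular
    margin = window + max_arm
    left = hit.offset - margin
    right = hit.offset + 9 + margin
    if circular:
        ctx = "".join(s[i % L] for i in range(left, right))
        c = margin  # nonamer start in ctx coords
        origin = left  # ctx position 0 maps to circle position origin (mod L)
    else:
        lo, hi = max(left, 0), min(right, L)
        ctx = s[lo:hi]
        c = hit.offset - lo
        origin = lo
    n = len(ctx)

    best: tuple[int, int, int] | None = None  # (-arm, loop_len, stem5_start_local)
    best_pair: tuple[int, int, int] | None = None  # (ls, le, arm)
    for ls in range(max(c + 9 - max_loop, 0), c + 1):
        for le in range(c + 9, min(ls + max_loop, n) + 1):
            # longest perfect arm adjacent to this loop
            arm = 0
            while (
                arm < max_arm
                and ls - arm - 1 >= 0
                and le + arm < n
                and ctx[ls - arm - 1] == _COMPLEMENT[ctx[le + arm]]
            ):
                arm += 1
            if arm < min_arm:
                continue
            key = (-arm, le - ls, ls - arm)
            if best is None or key < best:
                best = key
                best_pair = (ls, le, arm)
    if best_pair is None:
        return None
    ls, le, arm = best_pair
    # anchor at the 5' arm start, reduced mod L; downstream coordinates keep
    # their span and may exceed L, meaning the hairpin wraps the breakpoint
    stem5 = (origin + ls - arm) % L if circular else origin + ls - arm
    loop_len = le - ls
    return StemLoopHit(
        nonamer=hit,
        arm_len=arm,
        loop_start=stem5 + arm,
        loop_end=stem5 + arm + loop_len,
        stem5_start=stem5,
        stem3_end=stem5 + arm + loop_len + arm,
    )


_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "?"}


def scan_genome(
    seq: str,
    canonical: str = CANONICAL_NONAMER,
    max_mismatch: int = 1,
    min_arm: int = 5,
    max_arm: int = 20,
    max_loop: int = 15,
    window: int = 40,
    circular: bool = True,
) -> list[StemLoopHit]:
    """Nonamer scan + hairpin test; only nonamers inside a hairpin survive."""
    out: list[StemLoopHit] = []
    for hit in find_nonamer_sites(
        seq, canonical=canonical, max_mismatch=max_mismatch, circular=circular
    ):
        sl = detect_hairpin(
            seq,
            hit,
            min_arm=min_arm,
            max_arm=max_arm,
            max_loop=max_loop,
            window=window,
            circular=circular,
        )
        if sl is not None:
            out.append(sl)
    return out
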