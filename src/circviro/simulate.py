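"""Synthetic contig sets with the structure circular-virus discovery assumes.

The generator emits the kinds of sequences the pipeline is built to
recognize: circular genomes linearized with an assembler-style duplicated
end, stem-loop replication origins with a planted nonanucleotide, open
reading frames (optionally wrapping the circular breakpoint), low-complexity
dinucleotide runs, and point-mutation divergence at controlled rates — each
with a machine-readable truth record.

Planted features are guaranteed recoverable at the analysis modules' default
settings: the generator breaks base pairing just outside planted hairpin
arms so the recovered arm length is exact, and it sterilizes the random
background by writing an in-frame stop into any chance ORF that reaches the
caller's length threshold, so the ORF census equals the planted truth.

Randomness: a single integer seed drives one root `numpy` SeedSequence;
every contig draws from its own spawned substream, so the insertion order of
classes never changes downstream draws.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import reverse_complement

from .records import Contig, SimSpec, TruthRecord
from .orfs import find_orfs, plus_strand_interval
from .stemloop import CANONICAL_NONAMER, scan_genome

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_circular_genome(length: int, gc: float, seed) -> str:
    """I.i.d. random circle with the target G+C fraction."""
    if length < 100:
        raise ValueError("length must be >= 100")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


class FeatureMap:
    """Occupied intervals on a circle, to reject colliding plantings."""

    def __init__(self, length: int):
        self.length = length
        self.intervals: list[tuple[int, int]] = []  # (start, end), end may exceed L

    def _occupied(self, pos: int) -> bool:
        pos %= self.length
        for s, e in self.intervals:
            if s <= pos < e or s <= pos + self.length < e:
                return True
        return False

    def claim(self, start: int, end: int) -> None:
        if any(self._occupied(p) for p in range(start, end)):
            raise ValueError("planted feature collides with an existing feature")
        self.intervals.append((start % self.length, start % self.length + (end - start)))


def _write(seq: list[str], pos: int, text: str) -> None:
    L = len(seq)
    for i, ch in enumerate(text):
        seq[(pos + i) % L] = ch


def plant_stemloop(
    genome: str,
    offset: int,
    arm_len: int,
    nonamer: str = "TAGTATTAA",
    loop_len: int = 11,
    seed=0,
    features: FeatureMap | None = None,
) -> tuple[str, dict]:
    """Write a perfect hairpin with the nonamer in its loop at ``offset``.

    Layout, starting at ``offset``: one pairing-breaker base, the 5' arm, the
    loop (random padding then the nonamer), the 3' arm (exact reverse
    complement of the 5' arm), one pairing-breaker base. The breaker bases
    prevent chance outward extension of the stem, so the recovered arm length
    equals ``arm_len`` exactly.
    """
    if arm_len < 1 or loop_len < len(nonamer):
        raise ValueError("arm_len must be >= 1 and loop_len >= nonamer length")
    rng = _rng(seed)
    L = len(genome)
    pad = "".join(rng.choice(_BASES, size=loop_len - len(nonamer)))
    arm5 = "".join(rng.choice(_BASES, size=arm_len))
    block = "A" + arm5 + pad + nonamer + reverse_complement(arm5) + "A"
    total = len(block)
    if total > L:
        raise ValueError("stem-loop does not fit in the genome")
    if features is not None:
        features.claim(offset, offset + total)
    seq = list(genome)
    _write(seq, offset, block)
    truth = {
        "stem5_start": (offset + 1) % L,
        "arm_len": arm_len,
        "loop_len": loop_len,
        "nonamer_offset": (offset + 1 + arm_len + loop_len - len(nonamer)) % L,
        "nonamer": nonamer,
    }
    return "".join(seq), truth


def plant_orf(
    genome: str,
    start: int,
    length_nt: int,
    strand: str = "+",
    seed=0,
    features: FeatureMap | None = None,
) -> tuple[str, dict]:
    """Write an ORF (ATG, random non-stop codons, a stop) at ``start``.

    ``start``/``length_nt`` are plus-strand circle coordinates of the ORF's
    footprint; the frame may wrap the breakpoint. A stop codon is written
    immediately upstream in frame so the ORF cannot be extended by a chance
    in-frame ATG in the background, keeping the planted coordinates exact.
    """
    if length_nt % 3 != 0:
        raise ValueError("length_nt must be divisible by 3")
    if length_nt < 9:
        raise ValueError("length_nt must cover at least start + one codon + stop")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    rng = _rng(seed)
    L = len(genome)
    if length_nt + 3 > L:
        raise ValueError("ORF does not fit in the genome")
    n_internal = length_nt // 3 - 2
    codons = rng.choice(_NON_STOP_CODONS, size=n_internal) if n_internal else []
    stop = _STOPS[rng.integers(len(_STOPS))]
    orf_seq = "ATG" + "".join(codons) + stop
    guard = _STOPS[rng.integers(len(_STOPS))]  # upstream in-frame stop
    if strand == "+":
        block = guard + orf_seq
        block_start = start - 3
    else:
        # on the minus strand "upstream of ATG" sits at higher plus
        # coordinates: plus text over [start, start+len+3) is rc(guard+orf)
        block = reverse_complement(guard + orf_seq)
        block_start = start
    if features is not None:
        features.claim(block_start, block_start + len(block))
    seq = list(genome)
    _write(seq, block_start, block)
    truth = {"start": start % L, "length_nt": length_nt, "strand": strand}
    return "".join(seq), truth


def linearize_with_overlap(genome: str, breakpoint: int, overlap_len: int) -> str:
    """Rotate the circle to ``breakpoint`` and duplicate its first
    ``overlap_len`` bases at the end — the assembler's terminal-redundancy
    signature. ``overlap_len`` 0 yields a plain rotation (a linear-looking
    contig)."""
    L = len(genome)
    if not 0 <= breakpoint < L:
        raise ValueError("breakpoint out of range")
    if not 0 <= overlap_len < L:
        raise ValueError("overlap_len out of range")
    rot = genome[breakpoint:] + genome[:breakpoint]
    return rot + rot[:overlap_len]


def mutate(
    seq: str, divergence: float, indel_rate: float = 0.0, seed=0
) -> tuple[str, dict]:
    """Point-mutate a sequence at the given per-site substitution rate.

    Each position is substituted with probability ``divergence``, uniformly
    over the three alternatives. Indels (length 1-3, geometric) occur at
    ``indel_rate`` per site, insertion or deletion with equal probability.
    Returns the mutant and the realized event counts.
    """
    if divergence > 0.5:
        raise ValueError("divergence must be <= 0.5")
    rng = _rng(seed)
    out = []
    n_sub = n_ins = n_del = 0
    i = 0
    chars = list(seq)
    while i < len(chars):
        if indel_rate > 0 and rng.random() < indel_rate:
            size = min(int(rng.geometric(0.5)), 3)
            if rng.random() < 0.5:
                out.append("".join(rng.choice(_BASES, size=size)))
                n_ins += size
                continue  # insertion before position i; revisit i
            else:
                i += size
                n_del += size
                continue
        base = chars[i]
        if rng.random() < divergence:
            alt = [b for b in "ACGT" if b != base]
            base = alt[rng.integers(3)]
            if base != chars[i]:
                n_sub += 1
        out.append(base)
        i += 1
    return "".join(out), {"n_sub": n_sub, "n_ins": n_ins, "n_del": n_del}


def _sterilize_background(
    genome: str,
    planted: FeatureMap,
    min_len: int,
    rng: np.random.Generator,
    max_rounds: int = 30,
) -> str:
    """Disrupt chance background ORFs so only planted ORFs reach min_len.

    Any ORF at or above the caller's threshold whose start is not a planted
    ORF start is killed by overwriting one of its codons (chosen at a
    position clear of every planted feature) with a stop, in the ORF's own
    frame and strand. Iterates because an edit can shift reading frames
    elsewhere.
    """
    L = len(genome)

    def is_planted(rec) -> bool:
        ps, _ = plus_strand_interval(rec, L)
        return planted._occupied(ps)

    for _ in range(max_rounds):
        dirty = [
            rec
            for rec in find_orfs(genome, min_len=min_len, circular=True)
            if not is_planted(rec)
        ]
        if not dirty:
            return genome
        seq = list(genome)
        for rec in dirty:
            ps, _ = plus_strand_interval(rec, L)
            # candidate codon slots within the ORF, skipping start and stop
            slots = list(range(1, rec.length_nt // 3 - 1))
            rng.shuffle(slots)
            for slot in slots:
                if rec.strand == "+":
                    pos = (ps + 3 * slot) % L
                else:
                    pos = (ps + rec.length_nt - 3 * (slot + 1)) % L
                if any(planted._occupied((pos + k) % L) for k in range(3)):
                    continue
                stop = _STOPS[rng.integers(len(_STOPS))]
                text = stop if rec.strand == "+" else reverse_complement(stop)
                _write(seq, pos, text)
                break
        genome = "".join(seq)
    raise RuntimeError("could not sterilize background ORFs")


def _random_orf_layout(
    L: int,
    n_orfs: int,
    rng: np.random.Generator,
    min_len: int = 300,
    features: FeatureMap | None = None,
) -> list[tuple[int, int, str]]:
    """Non-colliding (start, length, strand) triples for planted ORFs.

    When ``features`` is given its claimed intervals (e.g. a planted
    stem-loop) are avoided, and the successful layout is claimed into it.
    """
    base_intervals = list(features.intervals) if features is not None else []
    for _ in range(200):
        layout = []
        occupied = FeatureMap(L)
        occupied.intervals = list(base_intervals)
        ok = True
        for _ in range(n_orfs):
            placed = False
            for _ in range(100):
                length = 3 * int(rng.integers(min_len // 3, min(min_len * 3, L // 2) // 3))
                start = int(rng.integers(L))
                strand = "+" if rng.random() < 0.5 else "-"
                lo = start - 3 if strand == "+" else start
                try:
                    occupied.claim(lo, lo + length + 3)
                except ValueError:
                    continue
                layout.append((start, length, strand))
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            if features is not None:
                features.intervals = occupied.intervals
            return layout
    raise ValueError("could not place ORFs: genome too small for the request")


def _build_circle(
    clazz: str,
    length: int,
    gc: float,
    n_orfs: int,
    with_stemloop: bool,
    rng: np.random.Generator,
    min_orf_len: int = 300,
) -> tuple[str, dict]:
    """One synthetic circle with verified-recoverable planted features."""
    for attempt in range(20):
        genome = random_circular_genome(length, gc, rng)
        features = FeatureMap(length)
        truth: dict = {"stemloop": None, "orfs": []}
        try:
            if with_stemloop:
                arm = int(rng.integers(6, 13))
                loop = int(rng.integers(9, 14))
                offset = int(rng.integers(length))
                genome, sl = plant_stemloop(
                    genome, offset, arm, loop_len=loop, seed=rng, features=features
                )
                truth["stemloop"] = sl
            for start, olen, strand in _random_orf_layout(
                length, n_orfs, rng, min_len=min_orf_len, features=features
            ):
                genome, ot = plant_orf(genome, start, olen, strand, seed=rng)
                truth["orfs"].append(ot)
            genome = _sterilize_background(genome, features, min_orf_len, rng)
        except (ValueError, RuntimeError):
            continue
        # verification pass: planted features must be recovered exactly
        orfs = find_orfs(genome, min_len=min_orf_len, circular=True)
        want = {(o["start"], o["length_nt"], o["strand"]) for o in truth["orfs"]}
        got = set()
        for rec in orfs:
            ps, _ = plus_strand_interval(rec, length)
            got.add((ps, rec.length_nt, rec.strand))
        if got != want:
            continue
        if with_stemloop:
            hits = scan_genome(genome)
            match = [
                h
                for h in hits
                if h.arm_len == truth["stemloop"]["arm_len"]
                and h.nonamer.offset == truth["stemloop"]["nonamer_offset"]
            ]
            if len(hits) != 1 or not match:
                continue
        return genome, truth
    raise RuntimeError(f"failed to build a clean {clazz} circle")


def make_dataset(spec: SimSpec) -> tuple[list[Contig], list[TruthRecord]]:
    """Simulated contig set plus complete truth table.

    Classes: papillomavirus-sized circles (7 planted ORFs, no origin),
    CRESS-sized circles (stem-loop origin + 1-2 ORFs over 300 nt), short
    stem-loop circles (~850 nt, 1-2 shorter ORFs), and linear contigs.
    Circular classes are emitted with an assembler-style duplicated end;
    output order is shuffled deterministically.
    """
    root = np.random.SeedSequence(spec.seed)
    n_total = spec.n_papilloma + spec.n_cress + spec.n_short + spec.n_linear
    streams = [np.random.default_rng(s) for s in root.spawn(n_total + 1)]
    shuffler, streams = streams[0], streams[1:]
    contigs: list[Contig] = []
    truths: list[TruthRecord] = []
    plan = (
        [("papilloma", i) for i in range(spec.n_papilloma)]
        + [("cress", i) for i in range(spec.n_cress)]
        + [("short", i) for i in range(spec.n_short)]
        + [("linear", i) for i in range(spec.n_linear)]
    )
    for (clazz, idx), rng in zip(plan, streams):
        cid = f"{clazz}_{idx:03d}"
        if clazz == "linear":
            length = int(rng.integers(*spec.linear_len))
            seq = random_circular_genome(length, spec.gc, rng)
            contigs.append(Contig(cid, seq))
            truths.append(
                TruthRecord(cid, clazz, length, 0, 0, None, None, None, ())
            )
            continue
        if clazz == "papilloma":
            length = int(rng.integers(*spec.papilloma_len))
            n_orfs, with_sl, min_orf = 7, False, 300
        elif clazz == "cress":
            length = int(rng.integers(*spec.cress_len))
            n_orfs, with_sl, min_orf = int(rng.integers(1, 3)), True, 300
        else:  # short
            length = int(rng.integers(*spec.short_len))
            n_orfs, with_sl, min_orf = 1, True, 300
        genome, truth = _build_circle(
            clazz, length, spec.gc, n_orfs, with_sl, rng, min_orf_len=min_orf
        )
        breakpoint = int(rng.integers(length))
        overlap = int(rng.integers(spec.overlap_range[0], spec.overlap_range[1] + 1))
        contig_seq = linearize_with_overlap(genome, breakpoint, overlap)
        contigs.append(Contig(cid, contig_seq))
        sl = truth["stemloop"]
        truths.append(
            TruthRecord(
                contig_id=cid,
                clazz=clazz,
                true_length=length,
                breakpoint=breakpoint,
                overlap_len=overlap,
                stemloop_offset=sl["nonamer_offset"] if sl else None,
                stemloop_arm=sl["arm_len"] if sl else None,
                stemloop_loop=sl["loop_len"] if sl else None,
                orfs=tuple(
                    (o["start"], o["length_nt"], o["strand"]) for o in truth["orfs"]
                ),
            )
        )
    order = shuffler.permutation(len(contigs))
    contigs = [contigs[i] for i in order]
    truths = [truths[i] for i in order]
    return contigs, truths


def synthetic_gene(length: int = 1500, gc: float = 0.45, seed=0) -> str:
    """A random protein-coding-style linear gene (ATG ... stop), used as a
    stand-in L1 for demarcation-recovery experiments."""
    if length % 3 != 0:
        raise ValueError("length must be divisible by 3")
    rng = _rng(seed)
    codons = rng.choice(_NON_STOP_CODONS, size=length // 3 - 2)
    return "ATG" + "".join(codons) + _STOPS[rng.integers(len(_STOPS))]
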