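"""Dataclasses shared across the pipeline.

Coordinates are 0-based, half-open everywhere in memory; 1-based inclusive
coordinates appear only in GFF3 output, per that format's definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Contig:
    """A raw assembly sequence — the pipeline's input unit."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class LowComplexityRun:
    """A maximal perfect tandem repeat of a short unit (period 1 or 2)."""

    start: int
    end: int
    period: int
    unit: str

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CircularGenome:
    """A trimmed circular sequence with its circularity evidence.

    ``seq`` holds exactly one full circle (the assembler's duplicated end
    removed); ``overlap_len`` is the number of terminally redundant
    nucleotides that were trimmed off.
    """

    id: str
    seq: str
    overlap_len: int
    gc: float
    truncated_intervals: tuple[tuple[int, int], ...] = ()

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class NonamerHit:
    """A rolling-circle origin nonanucleotide match on a circular genome.

    ``offset`` is the 0-based position of the motif's first base on the plus
    strand of the circle; for a minus-strand hit the motif string is given as
    read on the minus strand.
    """

    motif: str
    offset: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class StemLoopHit:
    """A nonamer embedded in a perfect inverted-repeat hairpin.

    All coordinates are plus-strand circle positions, possibly wrapping the
    breakpoint (taken modulo the genome length).
    """

    nonamer: NonamerHit
    arm_len: int
    loop_start: int
    loop_end: int
    stem5_start: int
    stem3_end: int

    @property
    def loop_len(self) -> int:
        return self.loop_end - self.loop_start


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame on a circular (or linear) genome.

    ``start`` is the 0-based position of the first base of the start codon in
    the coordinates of the ORF's own strand (for the minus strand, positions
    count along the reverse complement, so position 0 is the plus strand's
    last base). ``end = start + length_nt`` may exceed the genome length,
    meaning the frame wraps the circular breakpoint. ``length_nt`` includes
    the stop codon; ``protein`` excludes it.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    frame: int
    length_nt: int
    crosses_breakpoint: bool
    protein: str


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment and its percent identity.

    Identity is 100 x matched columns / total alignment columns, so a gap
    column counts against identity (the SDT-style convention).
    """

    a_id: str
    b_id: str
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float


@dataclass(frozen=True)
class DemarcationCall:
    """The L1-based papillomavirus typing decision for one query."""

    query_id: str
    closest_ref_id: str
    identity_pct: float
    category: str  # new_type | subtype | variant

    @property
    def divergence_pct(self) -> float:
        return 100.0 - self.identity_pct


@dataclass(frozen=True)
class CandidateReport:
    """Per-contig evidence row emitted by the triage pipeline."""

    contig_id: str
    circular: bool
    overlap_len: int
    trimmed_len: int
    gc: float
    n_orfs: int
    has_stemloop: bool
    nonamer_motif: str
    category: str
    flags: str = ""


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated contig."""

    contig_id: str
    clazz: str
    true_length: int
    breakpoint: int
    overlap_len: int
    stemloop_offset: int | None
    stemloop_arm: int | None
    stemloop_loop: int | None
    orfs: tuple[tuple[int, int, str], ...]  # (start, length_nt, strand) on the circle
    divergence: float | None = None


@dataclass
class SimSpec:
    """Parameters of a simulated contig set.

    Class sizes and genome-length ranges default to the magnitudes of the
    study this generator emulates: papillomavirus-sized circles of ~8 kb
    carrying seven ORFs, CRESS-like circles of ~1.7-3 kb carrying a stem-loop
    origin plus 1-2 ORFs over 300 nt, short ~850 nt stem-loop circles
    (defective-molecule/multicomponent-sized), and linear contigs.
    """

    seed: int = 0
    n_papilloma: int = 4
    n_cress: int = 4
    n_short: int = 6
    n_linear: int = 6
    papilloma_len: tuple[int, int] = (7200, 8200)
    cress_len: tuple[int, int] = (1700, 3000)
    short_len: tuple[int, int] = (700, 1000)
    linear_len: tuple[int, int] = (500, 3000)
    gc: float = 0.45
    overlap_range: tuple[int, int] = (20, 60)
    divergence_set: tuple[float, ...] = ()
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_papilloma", "n_cress", "n_short", "n_linear"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("papilloma_len", "cress_len", "short_len", "linear_len"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range is empty")
        if any(not 0.0 <= d <= 0.5 for d in self.divergence_set):
            raise ValueError("divergences must lie in [0, 0.5]")
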