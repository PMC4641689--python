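"""Six-frame, circular-aware open reading frame prediction.

An ORF runs from a start codon (ATG by default) to the first in-frame stop
(TAA/TAG/TGA), stop included in the length. On a circular genome the scan is
performed on the doubled sequence so frames wrapping the assembly breakpoint
are found; each ORF is reported once with its start reduced modulo the
genome length, and no ORF may span more than one full circle. Nested ORFs
are suppressed: only the longest frame per (stop, strand) — the one opened
by the first ATG after the previous stop — is reported.

A stop-to-stop mode (every maximal inter-stop segment, no start codon
required) is provided for parity with EMBOSS getorf-style callers; some
short spliced genes (e.g. papillomaviral E4) lack their own start codon and
are only visible that way.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from .records import OrfRecord
from .circular import clean_seq

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)  # TAA, TAG, TGA


def translate(seq: str, frame_offset: int = 0) -> str:
    """Translate with the standard genetic code.

    Stops render as ``*``; a single trailing stop is trimmed. Any codon
    containing a character outside ACGT (an assembly N, typically)
    translates to ``X``. The trailing partial codon, if any, is dropped.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    s = seq.upper().replace("U", "T")[frame_offset:]
    aas = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        if codon in _STOPS:
            aas.append("*")
        else:
            aas.append(_TABLE.forward_table.get(codon, "X"))
    protein = "".join(aas)
    return protein[:-1] if protein.endswith("*") else protein


def find_orfs(
    seq: str,
    min_len: int = 300,
    circular: bool = True,
    stop_to_stop: bool = False,
    genome_id: str = "",
) -> list[OrfRecord]:
    """All ORFs of at least ``min_len`` nt (stop codon included), both strands.

    Coordinates in each :class:`OrfRecord` are on the ORF's own strand (the
    minus strand counts along the reverse complement); ``start`` is reduced
    modulo the genome length and ``end`` may exceed it, flagging a frame that
    wraps the circular breakpoint.
    """
    if min_len < 6:
        raise ValueError("min_len must cover at least a start and a stop codon")
    s = clean_seq(seq)
    L = len(s)
    if L < 3:
        raise ValueError("genome shorter than one codon")
    records: list[OrfRecord] = []
    for strand, strand_seq in (("+", s), ("-", reverse_complement(s))):
        scan = strand_seq + strand_seq if circular else strand_seq
        for frame in range(3):
            start: int | None = None  # opening position of the current ORF
            opened_by_start_codon = False
            if stop_to_stop:
                start, opened_by_start_codon = frame, True
            for p in range(frame, len(scan) - 2, 3):
                codon = scan[p : p + 3]
                if codon in _STOPS:
                    if start is not None:
                        length = p + 3 - start
                        if length >= min_len and length <= L and start < L:
                            records.append(
                                _make_record(
                                    scan, start, length, strand, L, genome_id
                                )
                            )
                    start = p + 3 if stop_to_stop else None
                elif start is None and codon == "ATG":
                    start = p
    # suppress nested frames: keep the longest ORF per (stop mod L, strand),
    # then report each surviving ORF once per (start mod L, strand)
    by_stop: dict[tuple[int, str], OrfRecord] = {}
    for rec in records:
        key = (rec.end % L, rec.strand)
        if key not in by_stop or rec.length_nt > by_stop[key].length_nt:
            by_stop[key] = rec
    seen: set[tuple[int, str]] = set()
    out = []
    for rec in sorted(by_stop.values(), key=lambda r: (r.start, r.strand)):
        key = (rec.start, rec.strand)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def _make_record(
    scan: str, start: int, length: int, strand: str, L: int, genome_id: str
) -> OrfRecord:
    orf_seq = scan[start : start + length]
    return OrfRecord(
        genome_id=genome_id,
        start=start % L,
        end=start % L + length,
        strand=strand,
        frame=start % 3,
        length_nt=length,
        crosses_breakpoint=start % L + length > L,
        protein=translate(orf_seq),
    )


def plus_strand_interval(rec: OrfRecord, genome_len: int) -> tuple[int, int]:
    """Plus-strand footprint ``(start, end)`` of an ORF, end possibly > L.

    For a plus-strand ORF this is ``(rec.start, rec.end)``. For a minus-
    strand ORF (whose coordinates count along the reverse complement) the
    occupied plus-strand interval is recovered by reflection.
    """
    if rec.strand == "+":
        return rec.start, rec.end
    start = (genome_len - (rec.end % genome_len)) % genome_len
    return start, start + rec.length_nt
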