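"""FASTA / GFF3 / TSV input and output.

FASTA goes through Biopython's SeqIO; record ids are taken up to the first
whitespace. GFF3 output is 1-based inclusive per the format definition, with
``Is_circular=true`` on the region and breakpoint-wrapping features split
into two parts sharing one ID, per the GFF3 convention for circular genomes.
"""

from __future__ import annotations

import sys
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import CandidateReport, CircularGenome, Contig, OrfRecord, StemLoopHit
from .orfs import plus_strand_interval


def read_contigs(path_or_handle) -> list[Contig]:
    """Read a multi-FASTA of contigs (description after the id ignored)."""
    return [
        Contig(rec.id, str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(path_or_handle, "fasta")
    ]


def read_fasta_dict(path_or_handle) -> dict[str, str]:
    """FASTA as an ordered id -> sequence mapping (nt or aa)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def read_alignment_rows(path_or_handle) -> list[str]:
    """Rows of an aligned FASTA (equal-length, gaps as '-')."""
    rows = [str(rec.seq).upper() for rec in SeqIO.parse(path_or_handle, "fasta")]
    if not rows:
        raise ValueError("empty alignment")
    return rows


def write_contigs(contigs: Iterable[Contig], handle: TextIO) -> None:
    SeqIO.write(
        (SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs),
        handle,
        "fasta",
    )


def write_circles(genomes: Iterable[CircularGenome], handle: TextIO) -> None:
    """Circularized genomes with `circular=true overlap=<k>` header tags."""
    SeqIO.write(
        (
            SeqRecord(
                Seq(g.seq),
                id=g.id,
                description=f"circular=true overlap={g.overlap_len}",
            )
            for g in genomes
        ),
        handle,
        "fasta",
    )


def write_truncation_log(
    genomes: Iterable[CircularGenome], handle: TextIO
) -> None:
    """TSV of low-complexity intervals removed per contig (original coords)."""
    handle.write("contig_id\tstart\tend\n")
    for g in genomes:
        for s, e in g.truncated_intervals:
            handle.write(f"{g.id}\t{s}\t{e}\n")


def write_stemloop_tsv(
    hits: Iterable[tuple[str, StemLoopHit]], handle: TextIO
) -> None:
    handle.write(
        "genome_id\tmotif\toffset\tstrand\tmismatches\t"
        "arm_len\tloop_len\tstem5_start\tstem3_end\n"
    )
    for genome_id, h in hits:
        handle.write(
            f"{genome_id}\t{h.nonamer.motif}\t{h.nonamer.offset}\t"
            f"{h.nonamer.strand}\t{h.nonamer.mismatches}\t{h.arm_len}\t"
            f"{h.loop_len}\t{h.stem5_start}\t{h.stem3_end}\n"
        )


def write_orfs_gff3(
    orfs: Iterable[OrfRecord], genome_len: int, handle: TextIO, genome_id: str
) -> None:
    """GFF3 of ORFs; wrapped ORFs split at the breakpoint with a shared ID."""
    handle.write("##gff-version 3\n")
    handle.write(f"##sequence-region {genome_id} 1 {genome_len}\n")
    handle.write(
        f"{genome_id}\tcircviro\tregion\t1\t{genome_len}\t.\t+\t.\t"
        f"ID=region:{genome_id};Is_circular=true\n"
    )
    for i, rec in enumerate(orfs):
        start, end = plus_strand_interval(rec, genome_len)
        oid = f"orf{i:03d}"
        attrs = f"ID={oid};crosses_breakpoint={str(rec.crosses_breakpoint).lower()}"
        if end <= genome_len:
            parts = [(start + 1, end)]
        else:
            parts = [(start + 1, genome_len), (1, end - genome_len)]
        for p_start, p_end in parts:
            handle.write(
                f"{genome_id}\tcircviro\tCDS\t{p_start}\t{p_end}\t.\t"
                f"{rec.strand}\t0\t{attrs}\n"
            )


def write_orf_proteins(
    orfs: Iterable[OrfRecord], handle: TextIO, genome_id: str
) -> None:
    for i, rec in enumerate(orfs):
        handle.write(
            f">{genome_id}|orf{i:03d} start={rec.start} strand={rec.strand} "
            f"len={rec.length_nt}\n{rec.protein}\n"
        )


def write_triage_tsv(reports: Iterable[CandidateReport], handle: TextIO) -> None:
    handle.write(
        "contig_id\tcircular\toverlap_len\ttrimmed_len\tgc\tn_orfs\t"
        "has_stemloop\tnonamer_motif\tcategory\tflags\n"
    )
    for r in reports:
        gc = f"{r.gc:.4f}" if r.circular else ""
        handle.write(
            f"{r.contig_id}\t{str(r.circular).lower()}\t{r.overlap_len}\t"
            f"{r.trimmed_len}\t{gc}\t{r.n_orfs}\t{str(r.has_stemloop).lower()}\t"
            f"{r.nonamer_motif}\t{r.category}\t{r.flags}\n"
        )


def log(msg: str, verbose: bool = True) -> None:
    if verbose:
        print(msg, file=sys.stderr)
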