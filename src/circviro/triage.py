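"""End-to-end candidate triage.

Each contig is normalized (low-complexity truncation, terminal-redundancy
trimming, canonical rotation), scanned for a stem-loop replication origin,
and ORF-called; the evidence is folded into one of five categories that
mirror how full-genome candidates are reasoned about in circular-DNA virus
discovery:

- ``papillomavirus_sized``: a ~7-8.5 kb circle carrying at least six ORFs —
  the size and coding density of a papillomavirus genome.
- ``cress_sized``: a 1.2-3.2 kb circle with a nonamer stem-loop origin —
  the size range of CRESS-DNA virus genomes.
- ``short_circular_defective_or_multicomponent``: a sub-1.2 kb circle with a
  stem-loop origin — retains replication signals but is too small for a full
  gene complement, as seen for defective molecules and components of
  multicomponent viruses.
- ``circular_unclassified``: circular but matching none of the above.
- ``not_circular``: no terminal redundancy detected.

Category names deliberately claim size and structure, not taxonomy:
homology evidence is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import CandidateReport, Contig
from . import circular as circ
from .orfs import find_orfs
from .stemloop import CANONICAL_NONAMER, scan_genome


@dataclass
class TriageConfig:
    """All module defaults in one place; every boundary is a config key."""

    min_overlap: int = 10
    max_overlap_frac: float = 0.5
    strict_unique_ends: bool = False
    lc_max_period: int = 2
    lc_min_run: int = 20
    max_n_frac: float = 0.05
    nonamer: str = CANONICAL_NONAMER
    max_mismatch: int = 1
    min_arm: int = 5
    max_arm: int = 20
    max_loop: int = 15
    window: int = 40
    orf_min_len: int = 300
    papilloma_size: tuple[int, int] = (6800, 8500)
    papilloma_min_orfs: int = 6
    cress_size: tuple[int, int] = (1200, 3200)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "TriageConfig":
        cfg = cls()
        for key, value in mapping.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key: {key}")
            current = getattr(cfg, key)
            if isinstance(current, tuple):
                if isinstance(value, str):
                    value = value.split(",")
                value = tuple(int(v) for v in value)
            elif isinstance(current, bool):
                value = value in (True, "true", "1", 1)
            else:
                value = type(current)(value)
            setattr(cfg, key, value)
        return cfg


def triage_contig(contig: Contig, config: TriageConfig | None = None) -> CandidateReport:
    """Evidence row and category for a single contig."""
    cfg = config or TriageConfig()
    flags = []
    if circ.n_fraction(contig.seq) > cfg.max_n_frac:
        return CandidateReport(
            contig_id=contig.id,
            circular=False,
            overlap_len=0,
            trimmed_len=contig.length,
            gc=float("nan"),
            n_orfs=0,
            has_stemloop=False,
            nonamer_motif="",
            category="not_circular",
            flags="high_N_skipped",
        )
    genome = circ.circularize(
        contig,
        min_overlap=cfg.min_overlap,
        max_overlap_frac=cfg.max_overlap_frac,
        max_period=cfg.lc_max_period,
        min_run=cfg.lc_min_run,
        strict_unique_ends=cfg.strict_unique_ends,
    )
    if genome is None:
        return CandidateReport(
            contig_id=contig.id,
            circular=False,
            overlap_len=0,
            trimmed_len=contig.length,
            gc=float("nan"),
            n_orfs=0,
            has_stemloop=False,
            nonamer_motif="",
            category="not_circular",
        )
    if genome.truncated_intervals:
        flags.append("low_complexity_truncated")
    hits = scan_genome(
        genome.seq,
        canonical=cfg.nonamer,
        max_mismatch=cfg.max_mismatch,
        min_arm=cfg.min_arm,
        max_arm=cfg.max_arm,
        max_loop=cfg.max_loop,
        window=cfg.window,
    )
    orfs = find_orfs(genome.seq, min_len=cfg.orf_min_len, circular=True)
    L = genome.length
    if cfg.papilloma_size[0] <= L <= cfg.papilloma_size[1] and len(orfs) >= cfg.papilloma_min_orfs:
        category = "papillomavirus_sized"
    elif hits and cfg.cress_size[0] <= L <= cfg.cress_size[1]:
        category = "cress_sized"
    elif hits and L < cfg.cress_size[0]:
        category = "short_circular_defective_or_multicomponent"
    else:
        category = "circular_unclassified"
    return CandidateReport(
        contig_id=contig.id,
        circular=True,
        overlap_len=genome.overlap_len,
        trimmed_len=L,
        gc=genome.gc,
        n_orfs=len(orfs),
        has_stemloop=bool(hits),
        nonamer_motif=hits[0].nonamer.motif if hits else "",
        category=category,
        flags=";".join(flags),
    )


def triage(
    contigs: list[Contig], config: TriageConfig | None = None
) -> list[CandidateReport]:
    """Triage every contig; per-record failures are reported, not fatal."""
    cfg = config or TriageConfig()
    reports = []
    for contig in contigs:
        try:
            reports.append(triage_contig(contig, cfg))
        except ValueError as exc:
            reports.append(
                CandidateReport(
                    contig_id=contig.id,
                    circular=False,
                    overlap_len=0,
                    trimmed_len=contig.length,
                    gc=float("nan"),
                    n_orfs=0,
                    has_stemloop=False,
                    nonamer_motif="",
                    category="not_circular",
                    flags=f"error:{exc}",
                )
            )
    return reports
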