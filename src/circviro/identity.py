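"""Pairwise identity, SDT-style identity matrices, sliding-window identity,
and the L1-based papillomavirus demarcation decision.

Percent identity is defined as 100 x matched columns / total alignment
columns, so a gap column counts against identity. This is the convention the
species-demarcation style of analysis uses; it can differ by a few points
from definitions that ignore gap columns, which matters near classification
boundaries.

The demarcation rule operates on the L1 major capsid gene: an isolate whose
L1 differs by more than 10% from its closest known papillomavirus is a new
type; 2-10% divergence qualifies as a new subtype; under 2% a variant. The
caller is responsible for supplying L1 sequences — the functions here do not
verify gene identity.
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices
import numpy as np
import pandas as pd

from .records import DemarcationCall, PairwiseAlignment

_NT_CHARS = frozenset("ACGTUN-")


def _looks_nucleotide(seq: str) -> bool:
    return set(seq.upper()) <= _NT_CHARS


def make_aligner(
    alphabet: str = "nt",
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    """Global affine-gap aligner.

    Nucleotide scoring defaults to match +1 / mismatch -2; protein scoring
    uses BLOSUM62. ``gap_open`` is the score of the first gapped position, so
    a gap of length k scores ``gap_open + (k-1) * gap_extend``.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "aa":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    elif alphabet == "nt":
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    else:
        raise ValueError("alphabet must be 'nt' or 'aa'")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    a_id: str = "a",
    b_id: str = "b",
    aligner: Align.PairwiseAligner | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences with percent identity.

    The same alphabet is required for both inputs; alignments are scored
    with the supplied (or default nucleotide) scheme and the first alignment
    in the aligner's canonical order is taken, making the output
    deterministic.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    if _looks_nucleotide(a) != _looks_nucleotide(b):
        raise ValueError("mixed alphabets: one input looks nucleotide, the other protein")
    if aligner is None:
        aligner = make_aligner("nt" if _looks_nucleotide(a) else "aa")
    aln = aligner.align(a, b)[0]
    ga, gb = aln[0], aln[1]
    matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
    return PairwiseAlignment(
        a_id=a_id,
        b_id=b_id,
        aligned_a=ga,
        aligned_b=gb,
        score=float(aln.score),
        identity_pct=100.0 * matches / len(ga),
    )


def similarity_pct(alignment: PairwiseAlignment) -> float:
    """Protein similarity: identical or positively-scoring (BLOSUM62)
    residue pairs over all alignment columns."""
    blosum = substitution_matrices.load("BLOSUM62")
    sim = 0
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x == "-" or y == "-":
            continue
        if x == y or blosum[x, y] > 0:
            sim += 1
    return 100.0 * sim / len(alignment.aligned_a)


def identity_matrix(
    seqs: dict[str, str] | list[tuple[str, str]],
    aligner: Align.PairwiseAligner | None = None,
) -> pd.DataFrame:
    """All-vs-all percent-identity matrix (symmetric, diagonal 100)."""
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    ids = [i for i, _ in items]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(items)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pct = global_align(
                items[i][1], items[j][1], ids[i], ids[j], aligner=aligner
            ).identity_pct
            values[i, j] = values[j, i] = pct
    return pd.DataFrame(values, index=ids, columns=ids)


def sliding_window_identity(
    rows: list[str], window: int = 400, step: int = 50
) -> list[tuple[int, float]]:
    """Identity along a multiple alignment, in windows of columns.

    A column counts as identical when every row agrees exactly (a gap is a
    character like any other). Windows start at 0, step, 2*step, ...; the
    final partial window is reported with its actual width.
    """
    if not rows:
        raise ValueError("empty alignment")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows differ in length")
    length = len(rows[0])
    if window > length:
        raise ValueError("window exceeds alignment length")
    agree = [len({r[i] for r in rows}) == 1 for i in range(length)]
    out = []
    for start in range(0, length, step):
        width = min(window, length - start)
        ident = 100.0 * sum(agree[start : start + width]) / width
        out.append((start, ident))
        if start + window >= length:
            break
    return out


def classify_papillomavirus(
    query_l1: str,
    refs: dict[str, str] | list[tuple[str, str]],
    query_id: str = "query",
    aligner: Align.PairwiseAligner | None = None,
) -> DemarcationCall:
    """Type/subtype/variant call for a query L1 against reference L1 genes.

    The query is globally aligned to every reference; the closest reference
    (maximum identity) determines divergence d = 100 - identity, and the
    category follows the demarcation thresholds: d > 10 -> new_type,
    2 <= d <= 10 -> subtype, d < 2 -> variant.
    """
    items = list(refs.items()) if isinstance(refs, dict) else list(refs)
    if not items:
        raise ValueError("reference set is empty")
    if not query_l1:
        raise ValueError("empty query sequence")
    best_id, best_pct = None, -1.0
    for ref_id, ref_seq in items:
        pct = global_align(query_l1, ref_seq, query_id, ref_id, aligner=aligner).identity_pct
        if pct > best_pct:
            best_id, best_pct = ref_id, pct
    divergence = 100.0 - best_pct
    if divergence > 10.0:
        category = "new_type"
    elif divergence >= 2.0:
        category = "subtype"
    else:
        category = "variant"
    return DemarcationCall(
        query_id=query_id,
        closest_ref_id=best_id,
        identity_pct=best_pct,
        category=category,
    )
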