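"""Global alignment, identity matrices, sliding windows, demarcation calls."""

import itertools

import numpy as np
import pytest

from circviro import (
    classify_papillomavirus,
    global_align,
    identity_matrix,
    make_aligner,
    mutate,
    similarity_pct,
    sliding_window_identity,
    synthetic_gene,
)
from conftest import random_dna


def align_score_oracle(a, b, match, mismatch, gap_open, gap_extend):
    """Exhaustive enumeration of all global alignments (affine gaps: the
    first gapped position scores gap_open, subsequent ones gap_extend).
    Returns the optimal score. Feasible for lengths <= 7."""

    best = [-float("inf")]

    def walk(i, j, score, last_op):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, score + s, "m")
        if i < len(a):  # gap in b
            g = gap_extend if last_op == "gb" else gap_open
            walk(i + 1, j, score + g, "gb")
        if j < len(b):  # gap in a
            g = gap_extend if last_op == "ga" else gap_open
            walk(i, j + 1, score + g, "ga")

    walk(0, 0, 0.0, None)
    return best[0]


class TestGlobalAlign:
    def test_identical_sequences(self):
        assert global_align("ACGT", "ACGT").identity_pct == 100.0

    def test_one_mismatch_in_eight(self):
        aligner = make_aligner("nt", match=1, mismatch=-2, gap_open=-5, gap_extend=-5)
        aln = global_align("ACGTACGT", "ACGTACCT", aligner=aligner)
        assert len(aln.aligned_a) == 8
        assert aln.identity_pct == 87.5

    def test_single_gap_column(self):
        aln = global_align("AAAA", "AAA")
        assert aln.identity_pct == 75.0
        assert sorted([aln.aligned_a.count("-"), aln.aligned_b.count("-")]) == [0, 1]

    def test_degapping_recovers_inputs(self, rng):
        for _ in range(20):
            a, b = random_dna(rng, 40), random_dna(rng, 35)
            aln = global_align(a, b)
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b

    def test_matches_enumeration_oracle_on_short_strings(self, rng):
        batch = [random_dna(rng, int(rng.integers(1, 8))) for _ in range(8)]
        aligner = make_aligner("nt", match=1, mismatch=-2, gap_open=-10, gap_extend=-1)
        for a, b in itertools.combinations(batch, 2):
            got = global_align(a, b, aligner=aligner).score
            want = align_score_oracle(a, b, 1, -2, -10, -1)
            assert got == pytest.approx(want)

    def test_symmetry_of_identity(self, rng):
        for _ in range(10):
            a, b = random_dna(rng, 60), random_dna(rng, 55)
            assert global_align(a, b).identity_pct == pytest.approx(
                global_align(b, a).identity_pct
            )

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValueError):
            global_align("ACGT", "MKLW")
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_protein_alignment_and_similarity(self):
        aln = global_align("MKLIVW", "MKLLVW", aligner=make_aligner("aa"))
        assert aln.identity_pct < 100.0
        # I->L scores positively under BLOSUM62, so similarity exceeds identity
        assert similarity_pct(aln) > aln.identity_pct


class TestIdentityMatrix:
    def test_identical_pair(self):
        m = identity_matrix({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert m.loc["a", "b"] == 100.0

    def test_copy_ranks_above_diverged(self, rng):
        a = random_dna(rng, 200)
        b, _ = mutate(a, 0.2, seed=5)
        m = identity_matrix({"A": a, "B": b, "C": a})
        assert m.loc["A", "C"] == 100.0
        assert m.loc["A", "C"] > m.loc["A", "B"]

    def test_monotone_with_planted_distance(self):
        anc = synthetic_gene(600, seed=30)
        seqs = {"anc": anc}
        for i, d in enumerate([0.02, 0.06, 0.12, 0.25]):
            seqs[f"d{i}"] = mutate(anc, d, seed=40 + i)[0]
        m = identity_matrix(seqs)
        idents = [m.loc["anc", f"d{i}"] for i in range(4)]
        assert idents == sorted(idents, reverse=True)

    def test_matrix_invariants(self, rng):
        seqs = {f"s{i}": random_dna(rng, 80) for i in range(4)}
        m = identity_matrix(seqs)
        assert (m.values == m.values.T).all()
        assert (np.diag(m.values) == 100.0).all()
        assert ((m.values >= 0) & (m.values <= 100)).all()

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            identity_matrix([("x", "ACGT"), ("x", "ACGT")])


class TestSlidingWindow:
    def test_identical_rows(self):
        rows = ["ACGT" * 50] * 3
        assert all(pct == 100.0 for _, pct in sliding_window_identity(rows, 40, 20))

    def test_block_of_differences(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        assert sliding_window_identity([a, b], window=50, step=50) == [
            (0, 80.0),
            (50, 100.0),
        ]

    def test_short_alignment_single_window(self):
        assert sliding_window_identity(["ACGT", "ACGA"], window=4, step=50) == [
            (0, 75.0)
        ]

    def test_final_partial_window(self):
        rows = ["A" * 120, "A" * 120]
        track = sliding_window_identity(rows, window=50, step=50)
        assert track == [(0, 100.0), (50, 100.0), (100, 100.0)]

    def test_gap_counts_as_character(self):
        rows = ["AC-T", "AC-T", "ACGT"]
        assert sliding_window_identity(rows, window=4, step=4) == [(0, 75.0)]

    def test_bad_input_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_identity([], 10, 10)
        with pytest.raises(ValueError):
            sliding_window_identity(["ACGT", "ACG"], 2, 2)


class TestDemarcation:
    def test_published_thresholds(self):
        """82% identity is a new type; 99% a variant; 95% a subtype;
        boundaries d=10 and d=2 both fall in the subtype band."""
        ref = synthetic_gene(1500, seed=50)
        refs = {"ref": ref}

        def call_at(identity_target):
            d = (100.0 - identity_target) / 100.0
            # realized divergence may differ slightly; use the realized value
            mut, real = mutate(ref, d, seed=int(identity_target * 10))
            call = classify_papillomavirus(mut, refs)
            realized_d = 100.0 * real["n_sub"] / len(ref)
            return call, realized_d

        call, _ = call_at(82.0)
        assert call.category == "new_type"
        call, _ = call_at(99.0)
        assert call.category == "variant"
        call, _ = call_at(95.0)
        assert call.category == "subtype"

    def test_boundary_categories_exact(self):
        # engineered exact divergences on a gapless pair
        ref = "ACGT" * 250  # 1000 nt
        def with_divergence(n_subs):
            mutated = list(ref)
            for i in range(n_subs):
                pos = 4 * i  # distinct positions
                mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
            return "".join(mutated)

        assert classify_papillomavirus(with_divergence(100), {"r": ref}).category == "subtype"  # d=10
        assert classify_papillomavirus(with_divergence(101), {"r": ref}).category == "new_type"  # d>10
        assert classify_papillomavirus(with_divergence(20), {"r": ref}).category == "subtype"  # d=2
        assert classify_papillomavirus(with_divergence(19), {"r": ref}).category == "variant"  # d<2

    def test_category_monotone_in_identity(self):
        ref = "ACGT" * 250
        order = {"variant": 0, "subtype": 1, "new_type": 2}
        last = -1
        for n_subs in [0, 10, 19, 20, 60, 100, 101, 180, 250]:
            mutated = list(ref)
            for i in range(n_subs):
                mutated[4 * i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[4 * i]]
            call = classify_papillomavirus("".join(mutated), {"r": ref})
            assert order[call.category] >= last
            last = order[call.category]

    def test_closest_reference_wins(self, rng):
        anc = synthetic_gene(900, seed=60)
        near, _ = mutate(anc, 0.03, seed=61)
        far, _ = mutate(anc, 0.3, seed=62)
        call = classify_papillomavirus(anc, {"near": near, "far": far})
        assert call.closest_ref_id == "near"

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_papillomavirus("ACGT", {})
        with pytest.raises(ValueError):
            classify_papillomavirus("", {"r": "ACGT"})
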