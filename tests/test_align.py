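"""Global alignment against an exhaustive enumeration oracle."""
import random

import pytest
from Bio.Align import substitution_matrices

from venomkit.align import global_align, percent_identity
from venomkit.seqio import load_calcin_references, load_table2

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = 10.0, 0.5
AA = "ACDEFGHIKLMNPQRSTVWY"


def enumerate_best_score(a: str, b: str) -> float:
    """Best global affine-gap score by exhaustive enumeration of every
    alignment path (no dynamic programming)."""

    best = [float("-inf")]

    def walk(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + BLOSUM62[a[i]][b[j]], "m")
        if i < len(a):
            cost = GAP_EXTEND if last == "a" else GAP_OPEN
            walk(i + 1, j, score - cost, "a")
        if j < len(b):
            cost = GAP_EXTEND if last == "b" else GAP_OPEN
            walk(i, j + 1, score - cost, "b")

    walk(0, 0, 0.0, None)
    return best[0]


class TestGlobalAlign:
    def test_identical_strings(self):
        aln = global_align("PEPTIDE", "PEPTIDE")
        assert aln.n_identical == 7
        assert aln.aligned_a == aln.aligned_b == "PEPTIDE"

    def test_empty_vs_peptide(self):
        aln = global_align("", "PEPTIDE")
        assert aln.aligned_a == "-" * 7
        assert aln.n_identical == 0
        assert aln.score == pytest.approx(-(GAP_OPEN + GAP_EXTEND * 6))

    def test_gap_removal_recovers_inputs(self):
        rng = random.Random(21)
        for _ in range(50):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 40)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 40)))
            aln = global_align(a, b)
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b
            assert len(aln.aligned_a) == len(aln.aligned_b)
            assert aln.n_identical <= min(len(a), len(b))

    def test_score_equals_enumeration_oracle(self):
        rng = random.Random(22)
        pairs = [
            (
                "".join(rng.choice(AA) for _ in range(rng.randint(0, 6))),
                "".join(rng.choice(AA) for _ in range(rng.randint(0, 6))),
            )
            for _ in range(30)
        ]
        pairs += [
            (
                "".join(rng.choice(AA) for _ in range(8)),
                "".join(rng.choice(AA) for _ in range(8)),
            )
            for _ in range(3)
        ]
        for a, b in pairs:
            if not a and not b:
                continue
            assert global_align(a, b).score == pytest.approx(
                enumerate_best_score(a, b)
            ), (a, b)

    def test_illegal_residue(self):
        with pytest.raises(ValueError):
            global_align("PEPTXIDE", "PEPTIDE")


class TestPercentIdentity:
    def test_identical_is_100_under_both_definitions(self):
        assert percent_identity("PEPTIDE", "PEPTIDE") == 100.0
        assert percent_identity("PEPTIDE", "PEPTIDE", "shorter") == 100.0

    def test_symmetry(self):
        rng = random.Random(23)
        for _ in range(30):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 30)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 30)))
            assert percent_identity(a, b) == pytest.approx(percent_identity(b, a))

    def test_bounds_and_equality_condition(self):
        rng = random.Random(24)
        for _ in range(50):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 25)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 25)))
            pid = percent_identity(a, b)
            assert 0.0 <= pid <= 100.0

    def test_definitions_agree_when_gap_free(self):
        rng = random.Random(25)
        for _ in range(50):
            n = rng.randint(5, 30)
            a = "".join(rng.choice(AA) for _ in range(n))
            b = "".join(rng.choice(AA) for _ in range(n))
            aln = global_align(a, b)
            if "-" not in aln.aligned_a + aln.aligned_b:
                assert percent_identity(a, b) == pytest.approx(
                    percent_identity(a, b, "shorter")
                )

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            percent_identity("", "")

    def test_calcin_reference_identities(self):
        """The transcript calcin vs the packaged reference calcins: the
        quoted 69% (imperatoxin-A) and 87% (maurocalcin) identities."""
        comp749 = next(
            r.mature for r in load_table2() if r.name == "comp749_c0_seq1"
        )
        refs = {r.id: r.seq for r in load_calcin_references()}
        iptx = percent_identity(comp749, refs["P59868"])
        mauro = percent_identity(comp749, refs["P60254"])
        assert abs(iptx - 69) <= 1.0 or abs(round(iptx) - 69) <= 1
        assert abs(round(mauro) - 87) <= 1
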