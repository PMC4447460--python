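"""Global pairwise alignment and percent identity.

Cross-species comparisons of venom peptides are quoted as percent identity
from a global (Needleman-Wunsch) alignment.  The default scoring is BLOSUM62
with affine gaps (open 10, extend 0.5); identity counts are robust to the
exact scoring for the closely related pairs this is used on.

Two identity definitions are reported because published values rarely state
one: ``columns`` divides by the alignment length excluding terminal-gap
overhang, ``shorter`` divides by the length of the shorter sequence.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import AA_ALPHABET


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings differ in length")

    @property
    def n_identical(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )

    @property
    def core_length(self) -> int:
        """Alignment length excluding terminal-gap overhang."""
        cols = [
            i for i, (x, y) in enumerate(zip(self.aligned_a, self.aligned_b))
            if x != "-" and y != "-"
        ]
        if not cols:
            return 0
        return cols[-1] - cols[0] + 1

    def __str__(self) -> str:
        marks = "".join(
            "|" if x == y and x != "-" else " "
            for x, y in zip(self.aligned_a, self.aligned_b)
        )
        return f"{self.aligned_a}\n{marks}\n{self.aligned_b}"


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check(seq: str) -> None:
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"illegal residues for alignment: {sorted(bad)}")


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal global alignment of two peptides with affine gap penalties.

    The first optimal traceback is taken, which is deterministic for fixed
    inputs and scoring.  An empty sequence aligns all-gap against the other.
    """
    a, b = a.upper(), b.upper()
    _check(a)
    _check(b)
    if not a and not b:
        return PairwiseAlignment("", "", 0.0)
    if not a or not b:
        other = a or b
        gaps = "-" * len(other)
        score = -(gap_open + gap_extend * (len(other) - 1))
        return (
            PairwiseAlignment(gaps, other, score)
            if not a
            else PairwiseAlignment(other, gaps, score)
        )
    aln = _aligner(matrix, gap_open, gap_extend).align(a, b)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def percent_identity(
    a: str,
    b: str,
    definition: str = "columns",
    **scoring,
) -> float:
    """Percent identity from a global alignment.

    ``definition="columns"``: 100 x identical columns / alignment length
    excluding terminal-gap overhang.  ``definition="shorter"``: 100 x
    identical columns / length of the shorter input.
    """
    if not a and not b:
        raise ValueError("percent identity of two empty sequences is undefined")
    aln = global_align(a, b, **scoring)
    if definition == "columns":
        denom = aln.core_length
    elif definition == "shorter":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown identity definition {definition!r}")
    if denom == 0:
        return 0.0
    return 100.0 * aln.n_identical / denom
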