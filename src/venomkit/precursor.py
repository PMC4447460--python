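"""Precursor segmentation: signal peptide, propeptides, mature peptide and
C-terminal amidation.

Venom peptide precursors follow a small set of architectures:

* linear antimicrobial peptides (NDBPs): signal peptide, short amidated
  mature peptide, then an acidic C-terminal propeptide opened by a
  glycine-dibasic processing motif (GKR/GRR) whose glycine donates the
  C-terminal amide;
* cysteine-stabilised toxins: signal peptide, mature scaffold, optionally a
  single amide-donor glycine appended directly after the cysteine framework;
* a minority with an acidic N-terminal propeptide removed at a basic residue.

Signal cleavage is predicted by a transparent heuristic (von-Heijne-style):
the mean Kyte-Doolittle hydrophobicity of the candidate h-region scored
together with the (-3,-1) small-residue rule.  It is a stand-in for trained
signal-peptide predictors and is validated against the packaged curated
precursor fixture.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .seqio import AA_ALPHABET_X, SeqRecord

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

#: Residues accepted at the -3 and -1 positions of a signal cleavage site.
SMALL_RESIDUES = set("AGSCTV")

#: Default score threshold below which no signal peptide is called.
SIGNAL_SCORE_THRESHOLD = 1.5

#: Length prior on the cleavage position: score penalty per residue of
#: deviation from the typical signal length, and that typical length.
LENGTH_PRIOR_WEIGHT = 0.15
TYPICAL_SIGNAL_LEN = 24

MIN_MATURE_LEN = 8
MOTIF_WINDOW = (8, 25)          # G position relative to signal end
ACIDIC_FRACTION = 0.20          # D/E enrichment marking a propeptide
PRO_N_LEN = (10, 30)


@dataclass(frozen=True)
class MotifHit:
    """A candidate processing motif: the position of the glycine and the
    motif class (G-dibasic tripeptide, G-basic dipeptide, or a precursor-
    terminal glycine)."""

    pos: int
    kind: Literal["tripeptide", "dipeptide", "terminal"]
    text: str


@dataclass
class SegmentationResult:
    """A precursor partitioned into ordered, disjoint segments that jointly
    cover the sequence: signal | pro_n | mature | amid_gly | pro_c.

    ``pro_c`` starts immediately after the amide-donor glycine and therefore
    includes the dibasic residues of a processing motif; the motif text
    itself is reported in ``motif``.
    """

    precursor: str
    signal_end: int
    pro_n: tuple[int, int] | None
    mature: tuple[int, int]
    amid_gly_pos: int | None
    pro_c: tuple[int, int] | None
    amidated: bool
    motif: str | None = None
    method_flags: list[str] = field(default_factory=list)

    @property
    def signal_seq(self) -> str:
        return self.precursor[: self.signal_end]

    @property
    def pro_n_seq(self) -> str:
        return self.precursor[slice(*self.pro_n)] if self.pro_n else ""

    @property
    def mature_seq(self) -> str:
        return self.precursor[slice(*self.mature)]

    @property
    def pro_c_seq(self) -> str:
        return self.precursor[slice(*self.pro_c)] if self.pro_c else ""

    def segments(self) -> list[tuple[str, tuple[int, int]]]:
        """(label, interval) pairs in order, omitting empty segments."""
        out: list[tuple[str, tuple[int, int]]] = []
        if self.signal_end:
            out.append(("signal", (0, self.signal_end)))
        if self.pro_n:
            out.append(("pro_n", self.pro_n))
        out.append(("mature", self.mature))
        if self.amid_gly_pos is not None:
            out.append(("amid_gly", (self.amid_gly_pos, self.amid_gly_pos + 1)))
        if self.pro_c:
            out.append(("pro_c", self.pro_c))
        return out


def _check_aa(seq: str) -> None:
    bad = set(seq) - AA_ALPHABET_X
    if bad:
        raise ValueError(f"illegal amino-acid characters {sorted(bad)}")


def predict_signal_cleavage(
    precursor: str,
    min_cut: int = 15,
    max_cut: int = 45,
    threshold: float = SIGNAL_SCORE_THRESHOLD,
) -> tuple[int, float] | None:
    """Heuristic signal-peptide cleavage site.

    Every cut position in [min_cut, max_cut] is scored as the mean
    Kyte-Doolittle hydrophobicity of the h-region (positions 5..cut-6), plus
    a +1.0 bonus when the residues at cut-3 and cut-1 are small (A, G, S, C,
    T or V), minus a mild length prior of 0.15 per residue of deviation from
    the typical 24-residue signal (without it the mean-hydrophobicity term
    systematically prefers the shortest hydrophobic window).  Returns the
    best (cut, score), or None when the precursor does not start with M, is
    shorter than 25 residues, or no cut reaches ``threshold``.
    """
    _check_aa(precursor)
    if len(precursor) < 25 or not precursor.startswith("M"):
        return None
    best: tuple[int, float] | None = None
    hi = min(max_cut, len(precursor) - 1)
    for cut in range(min_cut, hi + 1):
        h_region = precursor[5 : cut - 5]
        if not h_region:
            continue
        score = sum(KYTE_DOOLITTLE[a] for a in h_region) / len(h_region)
        if precursor[cut - 3] in SMALL_RESIDUES and precursor[cut - 1] in SMALL_RESIDUES:
            score += 1.0
        score -= LENGTH_PRIOR_WEIGHT * abs(cut - TYPICAL_SIGNAL_LEN)
        if best is None or score > best[1]:
            best = (cut, score)
    if best is None or best[1] < threshold:
        return None
    return best


def find_processing_motifs(seq: str) -> list[MotifHit]:
    """All candidate amide-donor glycines, ordered by position.

    Reports G-[KR]-[KR] tripeptides (preferred when overlapping a dipeptide),
    G-[KR] dipeptides, and a sequence-terminal glycine.
    """
    _check_aa(seq)
    hits: list[MotifHit] = []
    for i, aa in enumerate(seq):
        if aa != "G":
            continue
        if i + 2 < len(seq) and seq[i + 1] in "KR" and seq[i + 2] in "KR":
            hits.append(MotifHit(i, "tripeptide", seq[i : i + 3]))
        elif i + 1 < len(seq) and seq[i + 1] in "KR":
            hits.append(MotifHit(i, "dipeptide", seq[i : i + 2]))
        elif i == len(seq) - 1:
            hits.append(MotifHit(i, "terminal", "G"))
    return hits


def _acidic_fraction(seq: str) -> float:
    return (seq.count("D") + seq.count("E")) / len(seq) if seq else 0.0


def _terminal_amide_gly(precursor: str) -> bool:
    """A precursor-terminal glycine is accepted as amide donor only when it
    directly follows the cysteine framework (a Cys within the preceding four
    residues), the pattern shown by every amidated cysteine-scaffold row of
    the curated fixture; isolated terminal glycines on partial or enzyme
    sequences do not qualify."""
    return precursor.endswith("G") and "C" in precursor[-5:-1]


def segment(precursor: str, hint: str | None = None) -> SegmentationResult:
    """Partition a precursor into signal, propeptide(s) and mature peptide.

    Decision order after signal prediction:

    1. a G-[KR]-[KR] motif 8-25 residues past the signal whose downstream
       remainder is acidic-enriched (>= 25% D/E) ends the mature peptide and
       marks amidation; the C-propeptide follows the glycine;
    2. a terminal glycine directly after a cysteine framework marks
       amidation of the preceding residue;
    3. an acidic stretch of 10-30 residues ending in R immediately after the
       signal, followed by at least 20 residues, is an N-propeptide;
    4. otherwise everything after the signal is mature and not amidated.

    ``hint`` is an optional family label recorded in the method flags (it
    does not change the rules).
    """
    _check_aa(precursor)
    n = len(precursor)
    flags: list[str] = []
    if hint:
        flags.append(f"hint:{hint}")
    if n < 25:
        return SegmentationResult(
            precursor, 0, None, (0, n), None, None, False,
            method_flags=flags + ["too-short"],
        )

    sig = predict_signal_cleavage(precursor)
    if sig is None:
        s = 0
        flags.append("no-signal")
    else:
        s = sig[0]
        flags.append("signal-heuristic")

    # 1. glycine-dibasic processing motif followed by an acidic propeptide
    hits = [h for h in find_processing_motifs(precursor[s:]) if h.kind == "tripeptide"]
    window = [
        h for h in hits
        if MOTIF_WINDOW[0] <= h.pos <= MOTIF_WINDOW[1] and h.pos >= MIN_MATURE_LEN
    ]
    for h in window:
        g = s + h.pos
        remainder = precursor[g + len(h.text):]
        if remainder and _acidic_fraction(remainder) >= ACIDIC_FRACTION:
            extra = [f"extra-motif:{x.pos + s}" for x in window if x is not h]
            return SegmentationResult(
                precursor, s, None, (s, g), g,
                (g + 1, n) if g + 1 < n else None,
                True, motif=h.text,
                method_flags=flags + ["motif-boundary"] + extra,
            )

    # 2. amide-donor glycine at the precursor terminus
    if _terminal_amide_gly(precursor) and n - 1 - s >= MIN_MATURE_LEN:
        return SegmentationResult(
            precursor, s, None, (s, n - 1), n - 1, None, True,
            motif="terminal-G", method_flags=flags + ["terminal-g"],
        )

    # 3. acidic N-terminal propeptide ending at a basic residue; the first
    # (shortest) qualifying stretch wins so the boundary cannot drift into an
    # acidic mature region
    best_e = None
    for e in range(s + PRO_N_LEN[0], min(s + PRO_N_LEN[1], n - 20) + 1):
        stretch = precursor[s:e]
        if precursor[e - 1] == "R" and _acidic_fraction(stretch) >= ACIDIC_FRACTION:
            best_e = e
            break
    if best_e is not None:
        return SegmentationResult(
            precursor, s, (s, best_e), (best_e, n), None, None, False,
            method_flags=flags + ["pro-n-acidic"],
        )

    # 4. no processing evidence
    return SegmentationResult(
        precursor, s, None, (s, n), None, None, False, method_flags=flags,
    )


def infer_amidation(segmentation: SegmentationResult) -> bool:
    """True iff the segmentation carries an amide-donor glycine."""
    return (
        segmentation.amid_gly_pos is not None
        and segmentation.precursor[segmentation.amid_gly_pos] == "G"
    )


def dedupe_unique(records: Sequence[SeqRecord]) -> list[tuple[str, list[str]]]:
    """Group records by identical sequence, preserving first-occurrence order.

    Returns (sequence, [record ids]) pairs; the id lists keep input order.
    """
    groups: dict[str, list[str]] = {}
    for rec in records:
        groups.setdefault(rec.seq, []).append(rec.id)
    return list(groups.items())
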