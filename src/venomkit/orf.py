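"""Six-frame translation and precursor ORF selection.

Transcripts assembled de novo have no annotated reading frame or strand, so
candidate coding regions are enumerated on all six frames.  By default ORFs
are start-anchored (require ATG) because curated venom precursors begin with
a methionine; a stop-to-stop mode is available for partial transcripts.
Selection follows a longest-ORF convention with a deterministic tie-break.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from Bio.Seq import Seq

from .seqio import NT_ALPHABET, SeqRecord

START_ANCHORED = "start"
STOP_TO_STOP = "stop"


@dataclass(frozen=True)
class OrfCandidate:
    """A candidate coding region.

    ``start_nt``/``end_nt`` are 0-based half-open coordinates on the forward
    strand of the parent transcript (for '-' strand ORFs they delimit the
    covered forward-strand interval).  ``protein`` excludes the stop codon;
    ``partial`` is set when the ORF runs off the end of the sequence without
    a stop codon.
    """

    parent_id: str
    strand: Literal["+", "-"]
    frame: int
    start_nt: int
    end_nt: int
    protein: str
    partial: bool = False

    def __post_init__(self) -> None:
        if (self.end_nt - self.start_nt) % 3:
            raise ValueError("ORF length not a multiple of 3")


def translate(nt: str, frame: int = 0) -> str:
    """Translate one forward frame with the standard genetic code.

    Codons containing N become 'X', stops are rendered '*', and a trailing
    partial codon is dropped.
    """
    nt = nt.upper()
    bad = set(nt) - NT_ALPHABET
    if bad:
        raise ValueError(f"illegal nucleotide characters {sorted(bad)}")
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    sub = nt[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def _frame_orfs(
    rec_id: str, nt: str, strand: str, frame: int, min_aa: int, mode: str
) -> list[OrfCandidate]:
    """ORFs in one frame of one strand, with forward-strand coordinates."""
    prot = translate(nt, frame)
    n = len(nt)
    out = []

    def to_forward(aa_start: int, aa_end: int) -> tuple[int, int]:
        # aa positions -> nucleotide coords on the translated strand;
        # the interval covers the protein only (stop codon excluded)
        s = frame + 3 * aa_start
        e = frame + 3 * aa_end
        if strand == "+":
            return s, e
        return n - e, n - s

    segments: list[tuple[int, int, bool]] = []  # aa_start, aa_end, stopped
    if mode == START_ANCHORED:
        i = 0
        while True:
            m = prot.find("M", i)
            if m < 0:
                break
            stop = prot.find("*", m)
            if stop < 0:
                segments.append((m, len(prot), False))
                break
            segments.append((m, stop, True))
            i = stop + 1
    else:  # stop-to-stop open stretches
        start = 0
        for j, aa in enumerate(prot + "*"):
            if aa == "*":
                if j > start:
                    segments.append((start, j, j < len(prot)))
                start = j + 1
    for aa_start, aa_end, stopped in segments:
        protein = prot[aa_start:aa_end]
        if len(protein) < min_aa:
            continue
        s, e = to_forward(aa_start, aa_end)
        out.append(
            OrfCandidate(
                parent_id=rec_id,
                strand=strand,
                frame=frame,
                start_nt=s,
                end_nt=e,
                protein=protein,
                partial=not stopped,
            )
        )
    return out


def find_orfs(
    record: SeqRecord, min_aa: int = 40, mode: str = START_ANCHORED
) -> list[OrfCandidate]:
    """All ORFs of length >= ``min_aa`` on both strands, longest first.

    Ties are broken in favour of the '+' strand, then the lower forward-strand
    start coordinate.
    """
    nt = record.seq
    rc = str(Seq(nt).reverse_complement())
    cands: list[OrfCandidate] = []
    for frame in (0, 1, 2):
        cands += _frame_orfs(record.id, nt, "+", frame, min_aa, mode)
        cands += _frame_orfs(record.id, rc, "-", frame, min_aa, mode)
    cands.sort(key=lambda c: (-len(c.protein), c.strand == "-", c.start_nt))
    return cands


def select_precursor_orf(candidates: Sequence[OrfCandidate]) -> OrfCandidate | None:
    """The precursor-coding ORF under the longest-ORF convention (first of the
    sorted candidate list), or None when there is no candidate."""
    return candidates[0] if candidates else None
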