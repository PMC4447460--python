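"""Theoretical peptide masses under monoisotopic and average conventions,
with C-terminal amidation and disulfide-bridge deltas.

A peptide's neutral mass is the sum of its residue masses plus one water.
C-terminal amidation (OH -> NH2) subtracts 0.98402 Da (monoisotopic) /
0.9847 Da (average); each disulfide bridge removes two hydrogens.  Published
venom tables mix conventions row by row, so the profile reports all four
variants (mono/average x with/without bridges) and a closest-variant helper
rather than committing to one.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

# IUPAC standard amino-acid residue masses (Da).
RESIDUE_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
RESIDUE_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MONO = 18.010565
WATER_AVG = 18.01528
H_MONO = 1.007825
H_AVG = 1.00794
AMIDATION_MONO = 0.98402
AMIDATION_AVG = 0.9847

Kind = Literal["mono", "avg"]


class MassError(ValueError):
    """Raised for residues without a defined mass (X or illegal characters)."""


def peptide_mass(seq: str, kind: Kind = "mono") -> float:
    """Neutral mass of an unmodified peptide: residue masses plus one water."""
    table, water = (RESIDUE_MONO, WATER_MONO) if kind == "mono" else (RESIDUE_AVG, WATER_AVG)
    total = water
    for aa in seq.upper():
        try:
            total += table[aa]
        except KeyError:
            raise MassError(f"no defined mass for residue {aa!r}") from None
    return total


def apply_modifications(
    base: float, kind: Kind = "mono", amidated: bool = False, n_bridges: int = 0
) -> float:
    """Apply the C-terminal amidation delta and disulfide hydrogen losses."""
    if n_bridges < 0:
        raise ValueError("n_bridges must be >= 0")
    out = base
    if amidated:
        out -= AMIDATION_MONO if kind == "mono" else AMIDATION_AVG
    out -= n_bridges * 2 * (H_MONO if kind == "mono" else H_AVG)
    return out


@dataclass(frozen=True)
class MassProfile:
    """Masses of a mature peptide under the four reporting conventions.

    ``variants`` maps (kind, with_bridges) to a mass; ``mono_da``/``avg_da``
    are the bridge-subtracted conventions.  ``available`` is False when the
    peptide contains undetermined residues.
    """

    seq: str
    amidated: bool
    n_bridges: int
    variants: dict[tuple[Kind, bool], float] = field(default_factory=dict)
    available: bool = True
    warnings: tuple[str, ...] = ()

    @property
    def mono_da(self) -> float:
        return self.variants[("mono", True)]

    @property
    def avg_da(self) -> float:
        return self.variants[("avg", True)]

    def closest_variant(self, target: float) -> tuple[str, float]:
        """The convention whose mass lies closest to ``target`` (Da)."""
        if not self.available:
            raise MassError("mass profile unavailable (undetermined residues)")
        label = {
            ("mono", False): "mono",
            ("avg", False): "avg",
            ("mono", True): "mono-SS",
            ("avg", True): "avg-SS",
        }
        key = min(self.variants, key=lambda k: abs(self.variants[k] - target))
        return label[key], self.variants[key]


def mass_profile(mature, amidated: bool | None = None) -> MassProfile:
    """Mass profile of a mature peptide.

    ``mature`` is either a sequence string (with ``amidated`` given) or a
    :class:`~venomkit.precursor.SegmentationResult`.  The bridge count is
    floor(cysteines / 2); an odd cysteine count is flagged.
    """
    if amidated is None and hasattr(mature, "mature_seq"):
        seq, amidated = mature.mature_seq, mature.amidated
    else:
        seq = str(mature)
        amidated = bool(amidated)
    seq = seq.upper()
    n_cys = seq.count("C")
    n_bridges = n_cys // 2
    warnings = ("odd-cysteine-count",) if n_cys % 2 else ()
    if "X" in seq or not seq:
        return MassProfile(seq, amidated, n_bridges, {}, available=False,
                           warnings=warnings + ("undetermined-residues",))
    variants: dict[tuple[Kind, bool], float] = {}
    for kind in ("mono", "avg"):
        base = peptide_mass(seq, kind)
        variants[(kind, False)] = apply_modifications(base, kind, amidated, 0)
        variants[(kind, True)] = apply_modifications(base, kind, amidated, n_bridges)
    return MassProfile(seq, amidated, n_bridges, variants, warnings=warnings)
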