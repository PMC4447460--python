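"""Correlate theoretical peptide masses with an experimental proteome list.

Matching is on mass alone (retention time is carried through for reporting
but never used), with an absolute (Da) or relative (ppm) tolerance.  Every
theory x experiment pair within tolerance is reported, and each experimental
mass is additionally labelled with its nearest theoretical candidate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .seqio import ProteomeMass


@dataclass(frozen=True)
class MatchRecord:
    theory_name: str
    theory_da: float
    exp_rt_min: float
    exp_da: float

    @property
    def delta_da(self) -> float:
        return self.theory_da - self.exp_da

    @property
    def delta_ppm(self) -> float:
        return self.delta_da * 1e6 / self.exp_da


@dataclass(frozen=True)
class MatchReport:
    matches: tuple[MatchRecord, ...]
    nearest: tuple[MatchRecord | None, ...]  # per experimental mass
    n_exp_matched: int
    n_theory_matched: int
    tolerance: float
    unit: Literal["Da", "ppm"]

    def to_frame(self) -> pd.DataFrame:
        """Proteome-correlation style table of the within-tolerance pairs."""
        return pd.DataFrame(
            [
                {
                    "rt_min": m.exp_rt_min,
                    "exp_da": m.exp_da,
                    "theory_da": m.theory_da,
                    "name": m.theory_name,
                    "delta_da": m.delta_da,
                    "delta_ppm": m.delta_ppm,
                }
                for m in self.matches
            ]
        )


def _within(theory_da: float, exp_da: float, tol: float, unit: str) -> bool:
    delta = abs(theory_da - exp_da)
    if unit == "Da":
        return delta <= tol
    return delta * 1e6 / exp_da <= tol


def match_masses(
    theory: Sequence[tuple[str, float]],
    experiment: Sequence[ProteomeMass],
    tol: float = 1.0,
    unit: Literal["Da", "ppm"] = "Da",
) -> MatchReport:
    """All-pairs mass matching within tolerance.

    ``theory`` is (name, mass) pairs; ``experiment`` is the proteome list.
    Nearest-candidate ties break on smaller |delta|, then lower theory index.
    Empty inputs yield an empty report.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    matches: list[MatchRecord] = []
    matched_theory: set[int] = set()
    matched_exp: set[int] = set()
    nearest: list[MatchRecord | None] = []
    for j, exp in enumerate(experiment):
        best: tuple[float, int] | None = None
        for i, (name, m) in enumerate(theory):
            if _within(m, exp.mass_da, tol, unit):
                matches.append(MatchRecord(name, m, exp.rt_min, exp.mass_da))
                matched_theory.add(i)
                matched_exp.add(j)
            delta = abs(m - exp.mass_da)
            if best is None or delta < best[0]:
                best = (delta, i)
        if best is None:
            nearest.append(None)
        else:
            name, m = theory[best[1]]
            nearest.append(MatchRecord(name, m, exp.rt_min, exp.mass_da))
    return MatchReport(
        matches=tuple(matches),
        nearest=tuple(nearest),
        n_exp_matched=len(matched_exp),
        n_theory_matched=len(matched_theory),
        tolerance=tol,
        unit=unit,
    )
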