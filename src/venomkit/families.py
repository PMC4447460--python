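"""Rule-based classification of mature venom peptides.

Scorpion venom peptide families are recognisable from three cheap features
of the mature peptide: the cysteine count (i.e. the disulfide scaffold), the
length, and a few literal sequence motifs (the adjacent CC half-cystine pair
of knottin-type calcins/agatoxins, the GFGCP amino-terminal block of
defensins).  Rules live in a YAML file so users can add families; they are
evaluated most-specific-first and the first matching envelope fires.

Peptides matching no rule fall back to ``venom-protein/other`` when they
contain cysteine, to an NDBP length class when they contain none, and to
``unclassified`` when empty or containing undetermined residues (X).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

#: NDBP (non-disulfide-bridged peptide) length classes: short < 20 aa,
#: medium 20-35 aa, long > 35 aa.
NDBP_SHORT_MAX = 19
NDBP_MEDIUM_MAX = 35

FAMILIES = (
    "NDBP-short", "NDBP-medium", "NDBP-long", "defensin",
    "scorpine-like/beta-KTx", "alpha-KTx", "calcin", "DDH-calcin",
    "agatoxin-like-calcin", "La1-like", "ascaris-type-inhibitor",
    "NaTx-like", "allergen-like", "venom-protein/other", "unclassified",
)


@dataclass(frozen=True)
class FamilyRule:
    family: str
    priority: int
    length_range: tuple[int, int]
    cys_count: frozenset[int] | None = None
    motifs: tuple[str, ...] = ()

    def matches(self, seq: str, n_cys: int) -> bool:
        lo, hi = self.length_range
        if not lo <= len(seq) <= hi:
            return False
        if self.cys_count is not None and n_cys not in self.cys_count:
            return False
        return all(m in seq for m in self.motifs)


@dataclass(frozen=True)
class FamilyCall:
    family: str
    rule_id: str | None
    length: int
    cys_count: int
    matched_motifs: tuple[str, ...] = ()
    reason: str | None = None


def _parse_rules(doc: dict) -> list[FamilyRule]:
    rules = []
    for entry in doc["rules"]:
        rules.append(
            FamilyRule(
                family=entry["family"],
                priority=int(entry["priority"]),
                length_range=tuple(entry["length"]),
                cys_count=frozenset(entry["cys"]) if "cys" in entry else None,
                motifs=tuple(entry.get("motifs", [])),
            )
        )
    rules.sort(key=lambda r: r.priority)
    if len({r.priority for r in rules}) != len(rules):
        raise ValueError("rule priorities must be unique")
    return rules


def load_rules(path: str | Path | None = None) -> list[FamilyRule]:
    """Load classification rules from YAML (packaged defaults when no path)."""
    if path is None:
        text = resources.files("venomkit.data").joinpath("family_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    return _parse_rules(yaml.safe_load(text))


_DEFAULT_RULES: list[FamilyRule] | None = None


def default_rules() -> list[FamilyRule]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def classify(mature: str, rules: list[FamilyRule] | None = None) -> FamilyCall:
    """Assign a mature peptide to exactly one venom family.

    Deterministic: rules fire in priority order; the NDBP length classes and
    the cysteine-containing fallback close the rule chain.
    """
    mature = mature.upper()
    n = len(mature)
    n_cys = mature.count("C")
    if not mature:
        return FamilyCall("unclassified", None, 0, 0, reason="empty")
    if "X" in mature:
        return FamilyCall("unclassified", None, n, n_cys, reason="undetermined residues")
    for rule in rules if rules is not None else default_rules():
        if rule.matches(mature, n_cys):
            return FamilyCall(
                rule.family, f"p{rule.priority}", n, n_cys,
                matched_motifs=rule.motifs,
            )
    if n_cys == 0:
        if n <= NDBP_SHORT_MAX:
            fam = "NDBP-short"
        elif n <= NDBP_MEDIUM_MAX:
            fam = "NDBP-medium"
        else:
            fam = "NDBP-long"
        return FamilyCall(fam, "ndbp-length-class", n, 0)
    return FamilyCall("venom-protein/other", "cys-fallback", n, n_cys)
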