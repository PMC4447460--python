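"""End-to-end pipeline orchestration and small expression utilities.

``run`` executes read -> ORF -> segment -> classify -> mass -> match over a
transcript FASTA (or over the packaged curated fixtures), writing TSV
reports plus a JSON summary.  Per-record failures are logged to a dropped-
record table, never fatal; every input record appears exactly once across
the annotation output and the dropped log.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import families as _families
from . import seqio
from .massmatch import match_masses
from .mass import mass_profile
from .orf import find_orfs, select_precursor_orf
from .precursor import dedupe_unique, segment

log = logging.getLogger("venomkit")


def fpkm(fragments: float, mapped_total: float, length_bp: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if length_bp <= 0:
        raise ValueError("transcript length must be positive")
    if mapped_total <= 0:
        raise ValueError("mapped library size must be positive")
    if fragments < 0:
        raise ValueError("fragment count must be >= 0")
    return fragments * 1e9 / (mapped_total * length_bp)


@dataclass
class RunConfig:
    input_fasta: str | Path | None = None      # transcript FASTA (nucleotide)
    fixtures: bool = False                     # run on the packaged curated tables
    proteome: str | Path | None = None         # TSV mass list (rt, Da)
    tol_da: float | None = 1.0
    tol_ppm: float | None = None
    mass_convention: str = "avg"               # mono | avg | all (reporting)
    rules: str | Path | None = None
    out_dir: str | Path | None = None
    min_aa: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol_ppm is None and (self.tol_da is None or self.tol_da <= 0):
            raise ValueError("tolerance must be positive")
        if not self.fixtures and self.input_fasta is None:
            raise ValueError("either an input FASTA or fixtures=True is required")


def _mass_row(name: str, profile) -> dict:
    row = {
        "name": name,
        "mature_len": len(profile.seq),
        "cys_count": profile.seq.count("C"),
        "amidated": profile.amidated,
        "n_bridges": profile.n_bridges,
        "available": profile.available,
    }
    if profile.available:
        row.update(
            mono=round(profile.variants[("mono", False)], 4),
            avg=round(profile.variants[("avg", False)], 4),
            mono_ss=round(profile.variants[("mono", True)], 4),
            avg_ss=round(profile.variants[("avg", True)], 4),
        )
    return row


def run(config: RunConfig) -> dict:
    """Run the curation pipeline and return the JSON-style summary.

    Reports written to ``out_dir`` (when given): annotation.tsv,
    classification.tsv, masses.tsv, matches.tsv, dropped.tsv, summary.json.
    """
    rules = _families.load_rules(config.rules) if config.rules else None
    dropped: list[dict] = []
    annotations: list[dict] = []
    class_rows: list[dict] = []
    mass_rows: list[dict] = []
    theory: list[tuple[str, float]] = []
    precursor_records: list[seqio.SeqRecord] = []

    if config.fixtures:
        precursors = [(row.name, row.precursor) for row in seqio.load_table2()]
    else:
        precursors = []
        for rec in seqio.read_fasta(config.input_fasta, alphabet="nt"):
            cand = select_precursor_orf(find_orfs(rec, min_aa=config.min_aa))
            if cand is None:
                dropped.append({"name": rec.id, "reason": f"no ORF >= {config.min_aa} aa"})
                continue
            precursors.append((rec.id, cand.protein))

    for name, prec in precursors:
        try:
            seg = segment(prec)
        except ValueError as exc:
            dropped.append({"name": name, "reason": str(exc)})
            continue
        precursor_records.append(seqio.SeqRecord(id=name, seq=prec))
        call = _families.classify(seg.mature_seq, rules)
        profile = mass_profile(seg)
        annotations.append(
            {
                "name": name,
                "signal": seg.signal_seq,
                "pro_n": seg.pro_n_seq,
                "mature": seg.mature_seq,
                "amid_gly": "G" if seg.amid_gly_pos is not None else "",
                "pro_c": seg.pro_c_seq,
                "amidated": seg.amidated,
                "motif": seg.motif or "",
                "method_flags": ";".join(seg.method_flags),
            }
        )
        class_rows.append(
            {
                "name": name,
                "family": call.family,
                "rule_id": call.rule_id or "",
                "length": call.length,
                "cys_count": call.cys_count,
            }
        )
        mass_rows.append(_mass_row(name, profile))
        if profile.available:
            key = ("avg", True) if config.mass_convention != "mono" else ("mono", True)
            theory.append((name, profile.variants[key]))

    if config.fixtures and config.proteome is None:
        experiment = [
            seqio.ProteomeMass(rt, mw)
            for rt, mw in zip(seqio.load_table3()["rt_min"], seqio.load_table3()["exp_mw_da"])
        ]
    elif config.proteome is not None:
        experiment = seqio.load_proteome_masses(config.proteome)
    else:
        experiment = []

    if experiment and theory:
        tol, unit = (
            (config.tol_ppm, "ppm") if config.tol_ppm is not None else (config.tol_da, "Da")
        )
        report = match_masses(theory, experiment, tol=tol, unit=unit)
    else:
        report = match_masses(theory, [], tol=config.tol_da or 1.0)

    family_counts = pd.Series([r["family"] for r in class_rows]).value_counts().to_dict() if class_rows else {}
    summary = {
        "n_input": len(precursors) + len(dropped),
        "n_annotated": len(annotations),
        "n_dropped": len(dropped),
        "n_unique_precursors": len(dedupe_unique(precursor_records)),
        "family_counts": family_counts,
        "n_experimental_masses": len(experiment),
        "n_exp_matched": report.n_exp_matched,
        "n_theory_matched": report.n_theory_matched,
        "tolerance": report.tolerance,
        "tolerance_unit": report.unit,
        "seed": config.seed,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(annotations).to_csv(out / "annotation.tsv", sep="\t", index=False)
        pd.DataFrame(class_rows).to_csv(out / "classification.tsv", sep="\t", index=False)
        pd.DataFrame(mass_rows).to_csv(out / "masses.tsv", sep="\t", index=False)
        report.to_frame().to_csv(out / "matches.tsv", sep="\t", index=False)
        pd.DataFrame(dropped, columns=["name", "reason"]).to_csv(
            out / "dropped.tsv", sep="\t", index=False
        )
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    for d in dropped:
        log.warning("dropped %s: %s", d["name"], d["reason"])
    return summary
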