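"""Sequence and fixture input/output plus basic assembly statistics.

The pipeline touches three kinds of files: multi-record FASTA carrying
assembled transcripts (or protein sequences), a tab-separated experimental
proteome mass list (retention time in minutes, deconvoluted mass in daltons),
and the packaged curation fixtures transcribed from the source study's
precursor and proteome tables.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET_X = AA_ALPHABET | {"X"}


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a parsed record violates a structural invariant."""


@dataclass(frozen=True)
class SeqRecord:
    """An identified nucleotide or amino-acid sequence.

    ``seq`` is stored uppercase; ``alphabet`` is ``"nt"`` or ``"aa"`` and is
    checked lazily by :func:`validate_record`.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record with empty id")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteomeMass:
    """One experimental proteome component: LC retention time and mass."""

    rt_min: float
    mass_da: float

    def __post_init__(self) -> None:
        if self.mass_da <= 0:
            raise ValidationError(f"non-positive mass {self.mass_da}")
        if self.rt_min < 0:
            raise ValidationError(f"negative retention time {self.rt_min}")


@dataclass(frozen=True)
class PrecursorFixtureRow:
    """A curated precursor with its annotated segments.

    The full precursor is the concatenation
    ``signal + propeptide_n + mature + amid_gly + propeptide_c``; ``amid_gly``
    is the amide-donor glycine (``"G"`` when ``amidated`` else empty).
    """

    name: str
    signal: str
    propeptide_n: str
    mature: str
    amid_gly: str
    propeptide_c: str
    amidated: bool
    description: str = ""
    note: str = ""

    @property
    def precursor(self) -> str:
        return self.signal + self.propeptide_n + self.mature + self.amid_gly + self.propeptide_c

    @property
    def full_length(self) -> bool:
        """True for rows with an annotated signal peptide on an intact N-terminus."""
        return len(self.signal) >= 15 and self.precursor.startswith("M")


@dataclass(frozen=True)
class AssemblyStats:
    n_seqs: int
    total_nt: int
    mean_len: float
    n50: int


def validate_record(rec: SeqRecord, alphabet: str = "nt") -> None:
    """Check that ``rec.seq`` uses only the given alphabet (nt: ACGTN; aa: 20
    residues plus X)."""
    allowed = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET_X
    bad = set(rec.seq) - allowed
    if bad:
        raise ValidationError(f"record {rec.id!r}: illegal characters {sorted(bad)}")


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SeqRecord]:
    """Read a (wrapped or unwrapped) FASTA file.

    Order is preserved, sequences are uppercased and whitespace-stripped.
    When ``alphabet`` is given ("nt" or "aa"), illegal characters raise a
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    records = [
        SeqRecord(id=r.id, seq=str(r.seq), description=r.description)
        for r in _BioSeqIO.parse(str(path), "fasta")
    ]
    if alphabet is not None:
        allowed = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET_X
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(">"):
                    continue
                bad = set(line.upper()) - allowed
                if bad:
                    raise ParseError(
                        f"{path.name}:{lineno}: illegal {alphabet} characters {sorted(bad)}"
                    )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def load_proteome_masses(path: str | Path) -> list[ProteomeMass]:
    """Load a tab-separated proteome mass list (header required).

    Columns named ``rt_min`` / ``exp_mw_da`` are used when present; otherwise
    the first two columns are taken as (retention time, mass).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path.name}: {exc}") from exc
    if df.empty:
        return []
    if {"rt_min", "exp_mw_da"} <= set(df.columns):
        rt_col, mass_col = "rt_min", "exp_mw_da"
    else:
        rt_col, mass_col = df.columns[0], df.columns[1]
    out = []
    for i, row in df.iterrows():
        try:
            rt = float(row[rt_col])
            mw = float(row[mass_col])
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path.name}: non-numeric value in data row {i + 1}: "
                f"{row[rt_col]!r}, {row[mass_col]!r}"
            ) from exc
        out.append(ProteomeMass(rt_min=rt, mass_da=mw))
    return out


def load_precursor_fixture(path: str | Path) -> list[PrecursorFixtureRow]:
    """Load a precursor annotation TSV (fixture schema: name, signal, pro_n,
    mature, amid_gly, pro_c, amidated, description, note).

    Every row is validated: the mature peptide must be non-empty, all segments
    must use amino-acid characters, and an amidated row must carry a glycine
    in the ``amid_gly`` column.
    """
    path = Path(path)
    rows: list[PrecursorFixtureRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, rec in enumerate(reader, start=1):
            row = PrecursorFixtureRow(
                name=rec["name"],
                signal=(rec.get("signal") or "").upper(),
                propeptide_n=(rec.get("pro_n") or "").upper(),
                mature=(rec.get("mature") or "").upper(),
                amid_gly=(rec.get("amid_gly") or "").upper(),
                propeptide_c=(rec.get("pro_c") or "").upper(),
                amidated=(rec.get("amidated", "false").lower() == "true"),
                description=rec.get("description", ""),
                note=rec.get("note", "") or "",
            )
            if not row.mature:
                raise ValidationError(f"{path.name} row {i} ({row.name}): empty mature peptide")
            bad = set(row.precursor) - AA_ALPHABET_X
            if bad:
                raise ValidationError(
                    f"{path.name} row {i} ({row.name}): illegal residues {sorted(bad)}"
                )
            if row.amidated and row.amid_gly != "G":
                raise ValidationError(
                    f"{path.name} row {i} ({row.name}): amidated without a donor glycine"
                )
            rows.append(row)
    return rows


def _data_path(name: str):
    return resources.files("venomkit.data").joinpath(name)


def load_table2() -> list[PrecursorFixtureRow]:
    """The packaged precursor fixture (111 curated venom-gland precursors)."""
    with resources.as_file(_data_path("table2_precursors.tsv")) as p:
        return load_precursor_fixture(p)


def load_table3() -> pd.DataFrame:
    """The packaged transcriptome-vs-proteome correlation fixture (16 rows).

    Columns include the printed theoretical/experimental masses, the mature
    peptide of the printed sequence, and ``resolved_mature`` where the printed
    sequence column is inconsistent with the transcript name (see ``flags``).
    """
    with resources.as_file(_data_path("table3_proteome.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    for col in ("resolved_name", "resolved_mature", "flags"):
        df[col] = df[col].fillna("")
    for col in ("amidated", "resolved_amidated"):
        df[col] = df[col].map(lambda v: str(v).lower() == "true")
    return df


def load_calcin_references() -> list[SeqRecord]:
    """Packaged reference calcin sequences (imperatoxin-A and maurocalcin)."""
    with resources.as_file(_data_path("calcin_references.fasta")) as p:
        return read_fasta(p, alphabet="aa")


def assembly_stats(records: Sequence[SeqRecord]) -> AssemblyStats:
    """Summary statistics of an assembly, with N50 defined as the largest
    length L such that contigs of length >= L contain at least half of the
    assembled bases."""
    lengths = sorted((len(r) for r in records), reverse=True)
    total = sum(lengths)
    if not lengths:
        return AssemblyStats(0, 0, 0.0, 0)
    half = total / 2
    running = 0
    n50 = lengths[-1]
    for L in lengths:
        running += L
        if running >= half:
            n50 = L
            break
    return AssemblyStats(
        n_seqs=len(lengths),
        total_nt=total,
        mean_len=total / len(lengths),
        n50=n50,
    )
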