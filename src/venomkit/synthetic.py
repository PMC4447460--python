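"""Seeded generator of venom-gland-like transcript sets with ground truth.

Precursors are drawn from family templates anchored to curated exemplars:
cysteine scaffolds keep the exemplar inter-cysteine spacings (jittered by
one position), non-cysteine positions are redrawn from a background residue
distribution, and each family keeps its diagnostic features (CC doublet,
GFGCP block, length window, amide-donor glycine).  NDBP precursors follow
the antimicrobial-peptide grammar: a 23-24 residue signal peptide, a short
(< 20 aa) amidated mature peptide, a GKR processing motif and an acidic
31-46 residue C-terminal propeptide.

Every precursor is built so that its segmentation is unambiguous under the
pipeline's published rules (the "unambiguity constraints" below: no decoy
processing motifs with acidic remainders, no competing acidic N-stretches,
no accidental cleavage-site bonuses near the true site).  Sequences are
redrawn until the constraints hold, so on noiseless data the pipeline must
recover every boundary exactly; noise enters only through the simulated
proteome mass list (Gaussian mass error, dropout).

All randomness flows from one seeded NumPy generator; identical
configurations produce byte-identical outputs.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .mass import mass_profile
from .seqio import ProteomeMass, SeqRecord

SMALL = set("AGSCTV")
#: Background residue alphabet for scaffold positions (no cysteine; C is
#: placed only where the template scaffold dictates).
BACKGROUND = "ADEFGHIKLMNPQRSTVWY"
#: Mildly hydrophilic weights, roughly venom-peptide-like composition.
BACKGROUND_W = np.array(
    [8, 5, 6, 4, 7, 2, 6, 9, 8, 2, 5, 4, 5, 6, 7, 6, 6, 1, 3], dtype=float
)
HYDROPHOBIC_CORE = "LIF"       # h-region of synthetic signal peptides
ACIDIC = "DE"

#: Mature-peptide templates: curated exemplar scaffolds per family.  The
#: first two residues are kept literal (they stabilise the cleavage-site
#: scoring), cysteines are kept at (jittered) template spacings, everything
#: else is redrawn.  ``amidated`` appends the amide-donor glycine.
TEMPLATES = {
    "alpha-KTx": dict(scaffold="GDIKCSSTKECFRPCEEIGGCSNAKCINGKCRCYGCI",
                      amidated=True, window=(23, 42)),
    "calcin": dict(scaffold="KDCLKKLKLCKENKDCCSKSCKRRGTNIEKRCR",
                   amidated=False, window=(30, 36), motif="CC"),
    "DDH-calcin": dict(scaffold="DLPPSDEYGTCVRPRKCKPHLKCSKAQTCVDPKKGW",
                       amidated=False, pro_n=True, window=(33, 40)),
    "agatoxin-like-calcin": dict(
        scaffold="AEPAYAEARCIRRGRMCDHNKYGCCNNGPCRCNLFGTNCRCQRRGLFQ",
        amidated=False, window=(38, 55), motif="CC"),
    "La1-like": dict(
        scaffold="FGESCQAGKHIVPVGQQQIDSSTCTLYKCSNYNRKYALETTSCATLKLKSGCRMVPGAATAPFPNCCPMMMCK",
        amidated=True, window=(65, 85)),
    "ascaris-type-inhibitor": dict(
        scaffold="QSGGRGRCRGRGEVFTYCGTGCRLTCQNYRNPPQICTLQCFIGCVCRSGWVRDTRSGRCVRPSQCRR",
        amidated=False, window=(50, 100)),
    "NaTx-like": dict(
        scaffold="KDDYPRNFEGNCYRCKYLEIGYCDAICKMHKAETGYCSRSNLFCYCTGIEDEYVSARNFLYQQNLKINNEELKDFDGNTL",
        amidated=False, window=(52, 84)),
    "defensin": dict(scaffold="GFGCPLNRYQCHSHCLSIGRRGGYCAGFLRTTCTCYKNK",
                     amidated=False, window=(36, 40), keep_prefix=5, motif="GFGCP"),
    "scorpine-like/beta-KTx": dict(
        scaffold="KTTVGQKIKNAAKKVYNKAKDLIGQSEYGCPMVSTFCEQFCKMKKMNGDCDLLKCVCT",
        amidated=False, window=(51, 110)),
}
NDBP_FAMILIES = ("NDBP-short", "NDBP-medium", "NDBP-long")
ALL_FAMILIES = tuple(TEMPLATES) + NDBP_FAMILIES + ("allergen-like",)

#: Default family census of a generated venom-gland transcript set
#: (200 precursors; linear antimicrobial peptides and alpha-KTx scaffolds
#: dominate, as in non-Buthidae venom glands).
DEFAULT_CENSUS = {
    "NDBP-short": 30, "NDBP-medium": 15, "NDBP-long": 15,
    "defensin": 15, "scorpine-like/beta-KTx": 15, "alpha-KTx": 30,
    "calcin": 15, "DDH-calcin": 10, "agatoxin-like-calcin": 10,
    "La1-like": 20, "ascaris-type-inhibitor": 15, "NaTx-like": 10,
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_per_family: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CENSUS))
    signal_len_range: tuple[int, int] = (23, 24)
    ndbp_mature_range: tuple[int, int] = (10, 19)   # short class; mature < 20 aa
    pro_len_range: tuple[int, int] = (31, 46)       # acidic C-propeptide
    ddh_pro_n_range: tuple[int, int] = (14, 24)     # acidic N-propeptide
    acidic_fraction: float = 0.4
    utr_len_range: tuple[int, int] = (30, 150)
    n_decoys: int = 0
    mass_noise_sd: float = 0.5
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must be in [0, 1]")
        if any(v < 0 for v in self.n_per_family.values()):
            raise ValueError("family counts must be >= 0")
        unknown = set(self.n_per_family) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")


@dataclass
class TruthRecord:
    """Ground truth for one generated record."""

    name: str
    family: str
    precursor: str
    signal_end: int
    pro_n: tuple[int, int] | None
    mature: tuple[int, int]
    amid_gly_pos: int | None
    pro_c: tuple[int, int] | None
    amidated: bool
    mature_seq: str
    mass_avg_ss: float | None      # amidation-aware, bridge-subtracted average mass
    cds: tuple[int, int] | None = None   # forward-strand coords on the transcript
    strand: str | None = None
    frame: int | None = None


# ---------------------------------------------------------------------------
# precursor generation

def _draw(rng: np.random.Generator, k: int) -> str:
    p = BACKGROUND_W / BACKGROUND_W.sum()
    return "".join(rng.choice(list(BACKGROUND), size=k, p=p)) if k else ""


def _signal(rng: np.random.Generator, length: int) -> str:
    # M + n-region + hydrophobic core + QSDA c-region; the (-3,-1) small
    # residues occur only at the true cleavage site
    n_region = "".join(rng.choice(list("KNQR"), size=4))
    core = "".join(rng.choice(list(HYDROPHOBIC_CORE), size=length - 9))
    return "M" + n_region + core + "QSDA"


def _acidic_stretch(rng: np.random.Generator, length: int, frac: float,
                    forbid: str = "R") -> str:
    out = []
    for _ in range(length):
        if rng.random() < frac:
            out.append(ACIDIC[rng.integers(2)])
        else:
            aa = BACKGROUND[rng.integers(len(BACKGROUND))]
            while aa in forbid:
                aa = BACKGROUND[rng.integers(len(BACKGROUND))]
            out.append(aa)
    return "".join(out)


def _rescaffold(rng: np.random.Generator, scaffold: str, keep_prefix: int = 2) -> str:
    """Redraw non-cysteine positions of a template scaffold, jittering each
    inter-cysteine run length by at most one residue.

    The literal prefix is kept; zero-length runs stay zero (an adjacent CC
    doublet is preserved exactly) and runs never shrink to zero (no new CC
    doublets appear), so each family keeps its diagnostic cysteine texture.
    """
    prefix = scaffold[:keep_prefix]
    out = [prefix]
    for run in re.split("(C)", scaffold[keep_prefix:]):
        if run == "C":
            out.append("C")
            continue
        length = len(run)
        if length > 0:
            length = max(1, length + int(rng.integers(-1, 2)))
        out.append(_draw(rng, length))
    return "".join(out)


def _acidity(seq: str) -> float:
    return (seq.count("D") + seq.count("E")) / len(seq) if seq else 0.0


def _unambiguous(precursor: str, signal_end: int,
                 pro_n_end: int | None, motif_g: int | None) -> bool:
    """The grammar's unambiguity constraints (mirrors the segmentation
    rules' trigger conditions so that only the intended rule can fire):
    no decoy glycine-dibasic motif with an acidic remainder, and no competing
    acidic N-stretch ending in R before the true propeptide boundary.  The
    cleavage site itself needs no constraint: the synthetic signal's LIF
    h-region and QSDA c-region make the true cut's score exceed any
    competitor's by construction (any shifted h-region dilutes with c-region
    or n-region residues and pays the length prior)."""
    c = signal_end
    n = len(precursor)
    for m in re.finditer("(?=(G[KR][KR]))", precursor[c:]):
        g = m.start()
        if 8 <= g <= 25 and c + g != motif_g:
            rem = precursor[c + g + 3:]
            if rem and _acidity(rem) >= 0.20:
                return False
    for e in range(c + 10, min(c + 30, n - 20) + 1):
        if pro_n_end is not None and e >= pro_n_end:
            break
        if precursor[e - 1] == "R" and _acidity(precursor[c:e]) >= 0.20:
            return False
    return True


def _build_precursor(rng: np.random.Generator, family: str,
                     config: GeneratorConfig):
    """One (precursor, truth fields) draw; may violate the unambiguity
    constraints and be rejected by the caller."""
    lo, hi = config.signal_len_range
    sig = _signal(rng, int(rng.integers(lo, hi + 1)))
    c = len(sig)
    if family == "NDBP-short":
        mlo, mhi = config.ndbp_mature_range
        mature = _draw(rng, int(rng.integers(mlo, mhi + 1)))
        plo, phi = config.pro_len_range
        pro_c_body = _acidic_stretch(
            rng, int(rng.integers(plo, phi + 1)), config.acidic_fraction, forbid="")
        motif = "G" + "".join(rng.choice(list("KR"), size=2))
        prec = sig + mature + motif + pro_c_body
        g = c + len(mature)
        return prec, dict(
            signal_end=c, pro_n=None, mature=(c, g), amid_gly_pos=g,
            pro_c=(g + 1, len(prec)), amidated=True, motif_g=g,
        )
    if family in ("NDBP-medium", "NDBP-long"):
        length = int(rng.integers(20, 36)) if family == "NDBP-medium" else int(rng.integers(36, 61))
        mature = _draw(rng, length)
        prec = sig + mature
        return prec, dict(
            signal_end=c, pro_n=None, mature=(c, len(prec)), amid_gly_pos=None,
            pro_c=None, amidated=False, motif_g=None,
        )
    if family == "allergen-like":
        length = int(rng.integers(190, 241))
        chars = list(_draw(rng, length))
        for pos in rng.choice(np.arange(10, length - 5), size=4, replace=False):
            chars[pos] = "C"
        if chars[-1] == "G":
            chars[-1] = "K"
        prec = sig + "".join(chars)
        return prec, dict(
            signal_end=c, pro_n=None, mature=(c, len(prec)), amid_gly_pos=None,
            pro_c=None, amidated=False, motif_g=None,
        )
    tpl = TEMPLATES[family]
    mature = _rescaffold(rng, tpl["scaffold"], tpl.get("keep_prefix", 2))
    lo_w, hi_w = tpl["window"]
    if not lo_w <= len(mature) <= hi_w:
        return None, None  # outside the family envelope; caller redraws
    if "motif" in tpl and tpl["motif"] not in mature:
        return None, None
    if mature.endswith("G") and not tpl["amidated"]:
        mature = mature[:-1] + "K"
    pro_n = ""
    if tpl.get("pro_n"):
        plo, phi = config.ddh_pro_n_range
        pro_n = (
            "E"
            + _acidic_stretch(rng, int(rng.integers(plo, phi + 1)) - 3,
                              config.acidic_fraction)
            + "ER"
        )
    amid = "G" if tpl["amidated"] else ""
    prec = sig + pro_n + mature + amid
    m0 = c + len(pro_n)
    m1 = m0 + len(mature)
    return prec, dict(
        signal_end=c,
        pro_n=(c, m0) if pro_n else None,
        mature=(m0, m1),
        amid_gly_pos=m1 if amid else None,
        pro_c=None,
        amidated=bool(amid),
        motif_g=None,
    )


def generate_precursors(
    config: GeneratorConfig,
) -> tuple[list[SeqRecord], list[TruthRecord]]:
    """Draw family-templated precursors with exact segmentation ground truth."""
    rng = np.random.default_rng(config.seed)
    records: list[SeqRecord] = []
    truth: list[TruthRecord] = []
    idx = 0
    for family in ALL_FAMILIES:
        count = config.n_per_family.get(family, 0)
        for _ in range(count):
            for _attempt in range(200):
                prec, t = _build_precursor(rng, family, config)
                if prec is None:
                    continue
                pro_n_end = t["pro_n"][1] if t["pro_n"] else None
                if _unambiguous(prec, t["signal_end"], pro_n_end, t["motif_g"]):
                    break
            else:
                raise RuntimeError(f"could not satisfy grammar constraints for {family}")
            idx += 1
            name = f"syn{idx:04d}_{family.replace('/', '-')}"
            mature_seq = prec[slice(*t["mature"])]
            prof = mass_profile(mature_seq, amidated=t["amidated"])
            records.append(SeqRecord(id=name, seq=prec, description=f"synthetic {family}"))
            truth.append(
                TruthRecord(
                    name=name, family=family, precursor=prec,
                    signal_end=t["signal_end"], pro_n=t["pro_n"],
                    mature=t["mature"], amid_gly_pos=t["amid_gly_pos"],
                    pro_c=t["pro_c"], amidated=t["amidated"],
                    mature_seq=mature_seq,
                    mass_avg_ss=prof.avg_da if prof.available else None,
                )
            )
    return records, truth


# ---------------------------------------------------------------------------
# reverse transcription

_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
_STOPS = sorted(standard_dna_table.stop_codons)


def _encode(rng: np.random.Generator, protein: str) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)


def _top_orf_is(nt: str, start: int, end: int, strand: str) -> bool:
    """True when the ORF at (start, end, strand) is the unique longest
    start-anchored ORF of the transcript (ties included)."""
    target_len = (end - start) // 3
    n = len(nt)
    for st, seq in (("+", nt), ("-", str(Seq(nt).reverse_complement()))):
        for frame in range(3):
            sub = seq[frame:]
            prot = str(Seq(sub[: len(sub) - len(sub) % 3]).translate())
            i = 0
            while True:
                m = prot.find("M", i)
                if m < 0:
                    break
                stop = prot.find("*", m)
                length = (stop if stop >= 0 else len(prot)) - m
                s_nt = frame + 3 * m
                fwd = s_nt if st == "+" else n - (s_nt + 3 * length)
                if (st, fwd, fwd + 3 * length) != (strand, start, end) and length >= target_len:
                    return False
                i = (stop + 1) if stop >= 0 else len(prot)
    return True


def reverse_transcribe(
    records: Sequence[SeqRecord],
    config: GeneratorConfig,
    truth: Sequence[TruthRecord] | None = None,
) -> tuple[list[SeqRecord], list[TruthRecord] | None]:
    """Embed each protein in a transcript: uniform synonymous codons, a stop
    codon, random UTRs, random strand.

    Transcripts are redrawn until the planted CDS is the unique longest
    start-anchored ORF, so translating the truth coordinates recovers each
    precursor exactly and ORF selection is unambiguous.  When ``truth`` is
    given, a copy annotated with CDS coordinates is returned.
    """
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.utr_len_range
    out_nt: list[SeqRecord] = []
    out_truth = list(truth) if truth is not None else None
    for k, rec in enumerate(records):
        for _attempt in range(200):
            cds = _encode(rng, rec.seq) + _STOPS[rng.integers(len(_STOPS))]
            utr5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(lo, hi + 1))))
            utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(lo, hi + 1))))
            fwd = utr5 + cds + utr3
            start = len(utr5)
            end = start + 3 * len(rec.seq)   # protein span, stop excluded
            if rng.random() < 0.5:
                nt, strand = fwd, "+"
                s, e = start, end
            else:
                nt, strand = str(Seq(fwd).reverse_complement()), "-"
                s, e = len(fwd) - end, len(fwd) - start
            if _top_orf_is(nt, s, e, strand):
                break
        else:
            raise RuntimeError(f"could not plant an unambiguous CDS for {rec.id}")
        out_nt.append(SeqRecord(id=rec.id, seq=nt, description=rec.description))
        if out_truth is not None:
            out_truth[k] = replace(
                out_truth[k], cds=(s, e), strand=strand,
                frame=(s if strand == "+" else (len(nt) - e)) % 3,
            )
    return out_nt, out_truth


def make_decoys(config: GeneratorConfig, rng: np.random.Generator | None = None) -> list[SeqRecord]:
    """Housekeeping-like decoy proteins (random 100-300 aa, background
    composition with occasional cysteines)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    out = []
    for i in range(config.n_decoys):
        length = int(rng.integers(100, 301))
        body = list(_draw(rng, length))
        for pos in rng.choice(np.arange(length), size=max(1, length // 40), replace=False):
            body[pos] = "C"
        out.append(
            SeqRecord(
                id=f"decoy{i + 1:04d}",
                seq="M" + "".join(body),
                description="synthetic housekeeping-like decoy",
            )
        )
    return out


def synth_proteome(
    truth: Sequence[TruthRecord], config: GeneratorConfig
) -> list[ProteomeMass]:
    """A noisy experimental mass list from the true mature masses.

    Each peptide is retained with probability (1 - dropout); retained masses
    are perturbed with Gaussian noise of sd ``mass_noise_sd`` Da and given a
    random retention time in [10, 50] minutes.
    """
    rng = np.random.default_rng(config.seed + 3)
    out = []
    for t in truth:
        if t.mass_avg_ss is None:
            continue
        if rng.random() < config.dropout:
            continue
        mass = t.mass_avg_ss + rng.normal(0.0, config.mass_noise_sd)
        rt = 10.0 + 40.0 * rng.random()
        out.append(ProteomeMass(rt_min=round(rt, 2), mass_da=round(mass, 4)))
    return out


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    proteins: list[SeqRecord]
    transcripts: list[SeqRecord]
    truth: list[TruthRecord]
    proteome: list[ProteomeMass]


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Full synthetic bundle: precursors, transcripts (with decoys appended),
    ground truth and a noisy proteome mass list."""
    proteins, truth = generate_precursors(config)
    transcripts, truth = reverse_transcribe(proteins, config, truth)
    decoys = make_decoys(config)
    if decoys:
        decoy_nt, _ = reverse_transcribe(decoys, config)
        transcripts = transcripts + decoy_nt
    proteome = synth_proteome(truth, config)
    return SyntheticDataset(config, proteins + decoys, transcripts, truth, proteome)
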