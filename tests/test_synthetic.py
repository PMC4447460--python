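"""Generator contracts: determinism, grammar guarantees, noise behaviour."""
import math

import pytest

from venomkit.massmatch import match_masses
from venomkit.orf import find_orfs, select_precursor_orf, translate
from venomkit.synthetic import (
    DEFAULT_CENSUS,
    GeneratorConfig,
    generate_dataset,
    generate_precursors,
    reverse_transcribe,
    synth_proteome,
)


class TestGeneratePrecursors:
    def test_zero_counts_empty(self):
        recs, truth = generate_precursors(
            GeneratorConfig(n_per_family={}, seed=0)
        )
        assert recs == [] and truth == []

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_per_family={"kraken-toxin": 3})

    def test_seeded_reproducibility(self):
        a = generate_dataset(GeneratorConfig(seed=5, n_decoys=5))
        b = generate_dataset(GeneratorConfig(seed=5, n_decoys=5))
        assert [r.seq for r in a.transcripts] == [r.seq for r in b.transcripts]
        assert a.proteome == b.proteome
        c = generate_dataset(GeneratorConfig(seed=6, n_decoys=5))
        assert [r.seq for r in a.transcripts] != [r.seq for r in c.transcripts]

    def test_ndbp_short_grammar(self):
        recs, truth = generate_precursors(
            GeneratorConfig(n_per_family={"NDBP-short": 50}, seed=2)
        )
        assert len(recs) == 50
        for t in truth:
            mature = t.mature_seq
            assert len(mature) < 20
            assert "C" not in mature
            assert t.amidated
            assert t.precursor[t.amid_gly_pos] == "G"
            # signal and acidic C-propeptide lengths follow the grammar
            assert t.signal_end in (23, 24)
            assert t.pro_c is not None

    def test_truth_reconstruction(self, noiseless_dataset):
        for t in noiseless_dataset.truth:
            parts = [t.precursor[: t.signal_end]]
            if t.pro_n:
                parts.append(t.precursor[slice(*t.pro_n)])
            parts.append(t.mature_seq)
            if t.amid_gly_pos is not None:
                parts.append("G")
            if t.pro_c:
                parts.append(t.precursor[slice(*t.pro_c)])
            assert "".join(parts) == t.precursor

    def test_default_census(self, noiseless_dataset):
        assert len(noiseless_dataset.truth) == sum(DEFAULT_CENSUS.values()) == 200


class TestReverseTranscribe:
    def test_empty_input(self):
        nt, truth = reverse_transcribe([], GeneratorConfig(seed=0))
        assert nt == [] and truth is None

    def test_cds_truth_translates_back(self, noiseless_dataset):
        tr = {r.id: r for r in noiseless_dataset.transcripts}
        for t in noiseless_dataset.truth:
            nt = tr[t.name].seq
            s, e = t.cds
            sub = nt[s:e]
            if t.strand == "-":
                comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
                sub = "".join(comp[c] for c in reversed(sub))
            assert translate(sub) == t.precursor

    def test_round_trip_orf_recovery(self, noiseless_dataset):
        """find_orfs + selection recovers every planted precursor exactly."""
        tr = {r.id: r for r in noiseless_dataset.transcripts}
        for t in noiseless_dataset.truth:
            top = select_precursor_orf(find_orfs(tr[t.name]))
            assert top is not None
            assert top.protein == t.precursor
            assert (top.start_nt, top.end_nt, top.strand) == (*t.cds, t.strand)

    def test_zero_length_utrs_cds_spans_transcript(self):
        recs, truth = generate_precursors(
            GeneratorConfig(n_per_family={"alpha-KTx": 5}, seed=3)
        )
        cfg = GeneratorConfig(
            n_per_family={"alpha-KTx": 5}, seed=3, utr_len_range=(0, 0)
        )
        nt, truth = reverse_transcribe(recs, cfg, truth)
        for rec, t in zip(nt, truth):
            assert t.cds[1] - t.cds[0] == 3 * len(t.precursor)
            assert len(rec.seq) == 3 * len(t.precursor) + 3  # + stop codon


class TestSynthProteome:
    def test_dropout_one_empty(self):
        _, truth = generate_precursors(
            GeneratorConfig(n_per_family={"alpha-KTx": 10}, seed=4)
        )
        cfg = GeneratorConfig(
            n_per_family={"alpha-KTx": 10}, seed=4, dropout=1.0
        )
        assert synth_proteome(truth, cfg) == []

    def test_noiseless_full_recovery(self, noiseless_dataset):
        theory = [
            (t.name, t.mass_avg_ss)
            for t in noiseless_dataset.truth
            if t.mass_avg_ss is not None
        ]
        rep = match_masses(theory, noiseless_dataset.proteome, tol=0.01)
        assert rep.n_exp_matched == len(noiseless_dataset.proteome) == 200

    def test_noisy_recovery_near_normal_expectation(self):
        """With sd 0.5 Da noise and +-1.0 Da tolerance the per-peptide
        recovery probability is 2*Phi(2)-1 ~ 0.954; over ~1000 peptides the
        observed rate must exceed 95% of that expectation envelope."""
        census = {"alpha-KTx": 250, "NDBP-short": 250, "La1-like": 250,
                  "calcin": 250}
        cfg = GeneratorConfig(
            n_per_family=census, seed=8, mass_noise_sd=0.5, dropout=0.0
        )
        _, truth = generate_precursors(cfg)
        proteome = synth_proteome(truth, cfg)
        recovered = 0
        for t, p in zip(truth, proteome):
            if abs(t.mass_avg_ss - p.mass_da) <= 1.0:
                recovered += 1
        expected = 2 * 0.5 * (1 + math.erf(2 / math.sqrt(2))) - 1  # 2*Phi(2)-1
        rate = recovered / len(proteome)
        assert rate >= 0.95
        assert abs(rate - expected) < 0.03
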