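"""IO round-trips, fixture integrity and assembly statistics."""
import random

import pytest

from venomkit.seqio import (
    ParseError,
    SeqRecord,
    ValidationError,
    assembly_stats,
    load_precursor_fixture,
    load_proteome_masses,
    read_fasta,
    write_fasta,
)


def _random_records(rng, n, alphabet="ACGT"):
    return [
        SeqRecord(
            id=f"r{i}",
            seq="".join(rng.choice(alphabet) for _ in range(rng.randint(1, 300))),
        )
        for i in range(n)
    ]


class TestFasta:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert read_fasta(p) == []

    def test_single_record(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">a\nACGT\n")
        recs = read_fasta(p)
        assert len(recs) == 1 and recs[0].id == "a" and len(recs[0]) == 4

    @pytest.mark.parametrize("alphabet", ["ACGT", "ACDEFGHIKLMNPQRSTVWY"])
    def test_round_trip_identity(self, tmp_path, alphabet):
        rng = random.Random(42)
        records = _random_records(rng, 100, alphabet)
        p = tmp_path / "rt.fasta"
        write_fasta(records, p)
        back = read_fasta(p)
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in records]

    def test_lowercase_and_whitespace_normalised(self, tmp_path):
        p = tmp_path / "lc.fasta"
        p.write_text(">a desc here\nacg t\nTTaa\n")
        (rec,) = read_fasta(p)
        assert rec.seq == "ACGTTTAA"

    def test_illegal_character_names_line(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nACGT\n>b\nAZGT\n")
        with pytest.raises(ParseError, match=r":4"):
            read_fasta(p, alphabet="nt")

    def test_empty_id_rejected(self):
        with pytest.raises(ValidationError):
            SeqRecord(id="", seq="ACGT")


class TestProteomeMasses:
    def test_header_only(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("rt\tmass\n")
        assert load_proteome_masses(p) == []

    def test_single_row(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("rt\tmass\n1.0\t100.0\n")
        (m,) = load_proteome_masses(p)
        assert m.rt_min == 1.0 and m.mass_da == 100.0

    def test_non_numeric_mass_raises(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("rt\tmass\n1.0\tabc\n")
        with pytest.raises(ParseError):
            load_proteome_masses(p)

    def test_packaged_fixture_first_row(self, table3):
        assert len(table3) == 16
        assert table3["rt_min"][0] == pytest.approx(13.88)
        assert table3["exp_mw_da"][0] == pytest.approx(1433.54)


class TestPrecursorFixture:
    def test_empty_fixture(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("name\tsignal\tpro_n\tmature\tamid_gly\tpro_c\tamidated\tdescription\tnote\n")
        assert load_precursor_fixture(p) == []

    def test_packaged_rows_reconstruct(self, table2):
        assert len(table2) == 111
        for row in table2:
            assert row.mature
            assert row.precursor == (
                row.signal + row.propeptide_n + row.mature + row.amid_gly + row.propeptide_c
            )
            if row.amidated:
                assert row.amid_gly == "G"

    def test_known_rows(self, table2_by_name):
        r = table2_by_name["comp17_c0_seq1-4"]
        assert len(r.signal) == 23
        assert r.mature == "ILSAIWSGIKSLF"
        assert r.amidated
        r = table2_by_name["comp1991_c0_seq1-5"]
        assert r.mature == "KYAPTGGCPLSDALCARYCLKHNYGRSGKCDGSTCKCS"
        assert r.propeptide_c == "TKLPNIIVL"
        assert not r.amidated

    def test_validation_error_names_row(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            "name\tsignal\tpro_n\tmature\tamid_gly\tpro_c\tamidated\tdescription\tnote\n"
            "bad1\tMKV\t\t\t\t\tfalse\tx\t\n"
        )
        with pytest.raises(ValidationError, match="bad1"):
            load_precursor_fixture(p)


class TestAssemblyStats:
    def test_single_contig(self):
        st = assembly_stats([SeqRecord(id="a", seq="A" * 500)])
        assert st.n50 == 500 and st.total_nt == 500 and st.n_seqs == 1

    def test_uniform_lengths(self):
        st = assembly_stats([SeqRecord(id=str(i), seq="A" * 2) for i in range(3)])
        assert st.n50 == 2

    def test_empty(self):
        st = assembly_stats([])
        assert st.n50 == 0 and st.total_nt == 0

    def test_against_brute_force(self):
        rng = random.Random(7)
        for _ in range(200):
            lengths = [rng.randint(1, 2000) for _ in range(rng.randint(1, 60))]
            recs = [SeqRecord(id=str(i), seq="A" * L) for i, L in enumerate(lengths)]
            total = sum(lengths)
            # brute force: scan every candidate length
            expected = max(
                L for L in lengths if sum(x for x in lengths if x >= L) >= total / 2
            )
            assert assembly_stats(recs).n50 == expected
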