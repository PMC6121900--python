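"""PTM flat-file parsing, window derivation and window validation."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptmgrav.errors import RowParseError, TableFormatError, ValidationError
from ptmgrav.ptm_store import (
    AMINO_ACIDS,
    PTMRecord,
    expected_window,
    read_fasta,
    read_ptm_flatfile,
    validate_window,
    write_ptm_flatfile,
)
from ptmgrav.synthetic import SyntheticScenario, generate_scenario


class TestReferenceSites:
    def test_row_and_accession_counts(self, reference_sites):
        assert len(reference_sites) == 46
        counts = Counter(r.accession for r in reference_sites)
        assert counts == {
            "O00194": 1,
            "O43592": 7,
            "P17900": 9,
            "P07996": 17,
            "P25786": 12,
        }

    def test_verbatim_modification_text_preserved(self, reference_sites):
        r = reference_sites[0]
        assert r.accession == "O00194"
        assert r.raw_modification == "N-acetylthreonine"
        assert r.position == 2
        assert r.window == "MTDGDY"
        # cross-link partner qualifiers survive parsing untouched
        iso = [x for x in reference_sites if "interchain" in x.raw_modification]
        assert len(iso) == 11

    def test_only_anomalous_window_is_the_10mer(self, reference_sites):
        long_windows = [r for r in reference_sites if len(r.window) > 9]
        assert [(r.accession, r.position) for r in long_windows] == [("P25786", 39)]
        assert long_windows[0].window == "YTVGLKSKTH"


class TestFlatFileIO:
    def test_reference_round_trips_byte_stably(self, reference_sites, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_ptm_flatfile(reference_sites, p1)
        again = read_ptm_flatfile(p1)
        assert again == reference_sites
        write_ptm_flatfile(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_synthetic_records_round_trip(self, tmp_path):
        bundle = generate_scenario(
            SyntheticScenario(seed=11, n_proteins=250, n_selected_planted=120,
                              sites_per_protein=(4, 12))
        )
        assert len(bundle.ptm_records) >= 500
        p = tmp_path / "sim.tsv"
        write_ptm_flatfile(bundle.ptm_records, p)
        assert tuple(read_ptm_flatfile(p)) == bundle.ptm_records

    def test_empty_file_with_header_gives_empty_collection(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_ptm_flatfile([], p)
        assert read_ptm_flatfile(p) == []

    def test_bad_rows_collected_not_silently_dropped(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "accession\tmodification\tposition\twindow\tsources\tpubmed_ids\tasa\n"
            "P12345\tPhosphoserine\tnotanint\tAAAASAAAA\t\t\t\n"
            "P12346\tPhosphoserine\t10\tAAAASAAAA\t\t\t\n"
            "P12347\tPhosphoserine\t10\tAAAA5AAAA\t\t\t\n"
        )
        errors: list = []
        records = read_ptm_flatfile(p, errors=errors)
        assert len(records) == 1 and records[0].accession == "P12346"
        assert len(errors) == 2
        assert {e.row for e in errors} == {1, 3}
        with pytest.raises(TableFormatError):
            read_ptm_flatfile(p)

    def test_unknown_source_label_kept_with_warning(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text(
            "accession\tmodification\tposition\twindow\tsources\tpubmed_ids\tasa\n"
            "P12345\tPhosphoserine\t10\tAAAASAAAA\tMadeUpDB;UniProt\t123\t45.5\n"
        )
        warnings: list = []
        (rec,) = read_ptm_flatfile(p, warnings=warnings)
        assert rec.sources == ("MadeUpDB", "UniProt")
        assert rec.pubmed_ids == (123,)
        assert rec.asa == pytest.approx(45.5)
        assert len(warnings) == 1 and "MadeUpDB" in warnings[0]


class TestExpectedWindow:
    @pytest.mark.parametrize(
        "sequence,position,window",
        [
            ("MTDGDYDYLIKLLALGDSGVGKT", 2, "MTDGDY"),   # N-terminal truncation
            ("MDEQALLSSS", 1, "MDEQA"),                  # site at residue 1
            ("ACDEFGHIK", 5, "ACDEFGHIK"),               # centered 9-mer
            ("ACDEFGHIK", 9, "FGHIK"),                   # C-terminal truncation
        ],
    )
    def test_window_convention(self, sequence, position, window):
        assert expected_window(sequence, position) == window

    def test_position_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            expected_window("ACDEF", 6)
        with pytest.raises(ValidationError):
            expected_window("ACDEF", 0)

    @given(
        seq=st.text(alphabet=sorted(AMINO_ACIDS), min_size=5, max_size=60),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_window_length_formula_and_center(self, seq, data):
        pos = data.draw(st.integers(1, len(seq)))
        w = expected_window(seq, pos)
        assert len(w) == min(pos + 4, len(seq)) - max(pos - 4, 1) + 1
        assert 5 <= len(w) <= 9
        assert w[min(pos, 5) - 1] == seq[pos - 1]


class TestValidateWindow:
    def test_phosphothreonine_interior_site(self, reference_sites):
        (rec,) = [
            r for r in reference_sites
            if r.accession == "O43592" and r.raw_modification == "Phosphothreonine"
        ]
        chk = validate_window(rec)
        assert rec.window == "FASRTSKAF"
        assert chk.expected_center_index == 5
        assert chk.center_residue == "T"
        assert chk.chemistry_ok is True and chk.length_ok

    def test_the_10mer_is_flagged_but_retained(self, reference_sites):
        (rec,) = [r for r in reference_sites if r.accession == "P25786" and r.position == 39]
        chk = validate_window(rec)
        assert chk.length_ok is False
        assert chk.ok is False

    def test_constructed_centered_phosphoserine(self):
        rec = PTMRecord("P12345", "Phosphoserine", 20, "AAAASAAAA")
        chk = validate_window(rec)
        assert chk.center_residue == "S" and chk.chemistry_ok is True

    def test_chemistry_indeterminate_without_unique_target(self):
        rec = PTMRecord("P12345", "O-linked (Fuc)", 20, "AAAASAAAA")
        chk = validate_window(rec)
        assert chk.chemistry_ok is None
        assert chk.ok  # indeterminate does not fail a record

    def test_sequence_rederivation_catches_wrong_window(self):
        seq = "MTDGDYDYLIKLLALG"
        good = PTMRecord("P12345", "N-acetylthreonine", 2, "MTDGDY")
        bad = PTMRecord("P12345", "N-acetylthreonine", 2, "MTDGDYD")
        assert validate_window(good, seq).length_ok
        assert not validate_window(bad, seq).length_ok

    def test_reference_rows_pass_except_the_10mer(self, reference_sites):
        checks = [validate_window(r) for r in reference_sites]
        failing = [c for c in checks if not c.ok]
        assert len(failing) == 1
        assert failing[0].record.position == 39


class TestRecordInvariants:
    def test_position_must_be_positive(self):
        with pytest.raises(ValidationError):
            PTMRecord("P12345", "Phosphoserine", 0, "AAAASAAAA")

    def test_window_must_be_amino_acids(self):
        with pytest.raises(ValidationError):
            PTMRecord("P12345", "Phosphoserine", 5, "AAAAXAAAB1")


def test_read_fasta_handles_uniprot_and_bare_headers(tmp_path):
    p = tmp_path / "seqs.fasta"
    p.write_text(">sp|P12345|NAME_HUMAN desc\nMTDGDY\n>Q00001\nacdef\n")
    seqs = read_fasta(p)
    assert seqs == {"P12345": "MTDGDY", "Q00001": "ACDEF"}
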