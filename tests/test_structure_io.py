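"""File-format readers: PDB models, contacts, class strings, DSSP, tables."""

import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poorqa.structure_io import (
    FormatError,
    extract_domain,
    read_contact_rr,
    read_dssp,
    read_pdb,
    read_sa_prediction,
    read_score_table,
    read_ss_prediction,
)
from poorqa.synthetic import make_coil, write_pdb

TOY_PDB = textwrap.dedent("""\
    ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
    ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
    ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
    ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
    ATOM      5  CB  ALA A   1       2.000  -0.760  -1.200  1.00  0.00           C
    ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
    ATOM      7  CA  GLY A   2       3.960   2.850   0.050  1.00  0.00           C
    ATOM      8  C   GLY A   2       5.470   2.720   0.100  1.00  0.00           C
    ATOM      9  O   GLY A   2       6.010   1.610   0.120  1.00  0.00           O
    ATOM     10  N   VAL A   3       6.170   3.850   0.120  1.00  0.00           N
    ATOM     11  CA  VAL A   3       7.620   3.870   0.170  1.00  0.00           C
    ATOM     12  C   VAL A   3       8.180   5.280   0.220  1.00  0.00           C
    ATOM     13  O   VAL A   3       7.440   6.260   0.210  1.00  0.00           O
    ATOM     14  CB  VAL A   3       8.190   3.120  -1.040  1.00  0.00           C
    END
    """)


class TestReadPdb:
    def test_toy_model_construction(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB)
        model = read_pdb(path)
        assert model.model_id == "toy"
        assert [r.name for r in model.residues] == ["ALA", "GLY", "VAL"]
        assert "CB" not in model.residues[1].atoms  # GLY
        assert "CB" in model.residues[0].atoms

    def test_gapped_numbering_preserved(self, tmp_path):
        text = TOY_PDB
        for old, new in (("A   2", "A   6"), ("A   3", "A   9"),
                         ("A   1", "A   5")):
            text = text.replace(old, new)
        path = tmp_path / "gap.pdb"
        path.write_text(text)
        model = read_pdb(path)
        assert model.residue_numbers == [5, 6, 9]

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(FormatError):
            read_pdb(path)

    def test_hetatm_ignored(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            TOY_PDB.replace("END\n", "") +
            "HETATM   15  O   HOH A  99      10.000  10.000  10.000"
            "  1.00  0.00           O\nEND\n")
        assert len(read_pdb(path)) == 3

    def test_roundtrip_through_writer(self, tmp_path):
        model = make_coil(12, seed=5)
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_pdb(model, p1)
        once = read_pdb(p1)
        write_pdb(once, p2)
        twice = read_pdb(p2)
        assert [r.name for r in once.residues] == [r.name for r in twice.residues]
        assert once.residue_numbers == twice.residue_numbers
        for a, b in zip(once.residues, twice.residues):
            assert set(a.atoms) == set(b.atoms)
            for name in a.atoms:
                np.testing.assert_allclose(a.atoms[name], b.atoms[name],
                                           atol=1e-3)


class TestExtractDomain:
    def test_discontinuous_ranges_collapse_to_envelope(self, tmp_path):
        model = make_coil(30, seed=1)
        # renumber to 70..99 so the envelope rule is visible
        for k, res in enumerate(model.residues):
            res.number = 70 + k
        dom = extract_domain(model, [(77, 80), (90, 95)])
        assert dom.residue_numbers == list(range(77, 96))

    def test_single_interval_equals_direct_filter(self):
        model = make_coil(20, seed=2)
        dom = extract_domain(model, [(4, 11)])
        expected = [r.number for r in model.residues if 4 <= r.number <= 11]
        assert dom.residue_numbers == expected

    def test_full_interval_is_identity(self):
        model = make_coil(10, seed=3)
        assert extract_domain(model, [(1, 10)]).residue_numbers == \
            model.residue_numbers

    def test_empty_result_errors(self):
        model = make_coil(50, seed=4)
        with pytest.raises(FormatError):
            extract_domain(model, [(200, 300)])


class TestReadContactRR:
    def test_basic_pairs(self, tmp_path):
        path = tmp_path / "c.rr"
        path.write_text("1 9 0 8 0.9\n2 8 0 8 0.7\n")
        pred = read_contact_rr(path, n_res=10)
        assert sorted(pred.pairs) == [(1, 9, 0.9), (2, 8, 0.7)]

    def test_swapped_indices_canonicalised(self, tmp_path):
        path = tmp_path / "c.rr"
        path.write_text("9 1 0 8 0.9\n")
        assert read_contact_rr(path, n_res=10).pairs == [(1, 9, 0.9)]

    def test_out_of_range_dropped_with_warning(self, tmp_path):
        path = tmp_path / "c.rr"
        path.write_text("1 9 0 8 0.9\n3 99 0 8 0.8\n")
        with pytest.warns(UserWarning):
            pred = read_contact_rr(path, n_res=10)
        assert len(pred.pairs) == 1

    def test_comment_only_file_errors(self, tmp_path):
        path = tmp_path / "c.rr"
        path.write_text("# header\nPFRMAT RR\n")
        with pytest.raises(FormatError):
            read_contact_rr(path, n_res=10)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(rows=st.lists(st.tuples(st.integers(1, 30), st.integers(1, 30),
                                   st.floats(0, 1, allow_nan=False)),
                         min_size=1, max_size=50))
    def test_never_returns_invalid_pairs(self, rows, tmp_path_factory):
        path = tmp_path_factory.mktemp("rr") / "c.rr"
        path.write_text("\n".join(f"{i} {j} 0 8 {c:.3f}" for i, j, c in rows))
        try:
            pred = read_contact_rr(path, n_res=30)
        except FormatError:
            assert all(i == j for i, j, _ in rows)
            return
        seen = set()
        for i, j, c in pred.pairs:
            assert i < j
            assert (i, j) not in seen
            assert 0.0 <= c <= 1.0
            seen.add((i, j))


class TestClassStrings:
    def test_ss_length_and_classes(self, tmp_path):
        path = tmp_path / "p.ss"
        path.write_text("HHHHCCEE\n")
        assert read_ss_prediction(path).classes == "HHHHCCEE"

    def test_ss_eight_state_collapses(self, tmp_path):
        path = tmp_path / "p.ss"
        path.write_text("HGEBT-\n")
        assert read_ss_prediction(path).classes == "HCECCC"

    def test_ss_unknown_characters_error(self, tmp_path):
        path = tmp_path / "p.ss"
        path.write_text("HHXZ\n")
        with pytest.raises(FormatError):
            read_ss_prediction(path)

    def test_sa_mapping(self, tmp_path):
        path = tmp_path / "p.acc"
        path.write_text("e-e-\n")
        assert read_sa_prediction(path).classes == "ebeb"

    def test_wrapped_lines_concatenate(self, tmp_path):
        path = tmp_path / "p.ss"
        path.write_text("> target\nHHHH\nCCEE\n")
        assert read_ss_prediction(path).classes == "HHHHCCEE"


def _dssp_line(index, number, aa, ss8, acc):
    line = f"{index:5d}{number:5d} A {aa}  {ss8}"
    return line.ljust(34) + f"{acc:4d}"


class TestReadDssp:
    HEADER = "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n"

    def test_construction_and_collapse(self, tmp_path):
        body = "\n".join([
            _dssp_line(1, 1, "A", "H", 10),
            _dssp_line(2, 2, "A", "E", 50),
            _dssp_line(3, 3, "A", " ", 120),
        ])
        path = tmp_path / "x.dssp"
        path.write_text(self.HEADER + body + "\n")
        assert read_dssp(path) == [(1, "H", 10.0), (2, "E", 50.0),
                                   (3, "C", 120.0)]

    def test_g_collapses_to_h_and_breaks_skipped(self, tmp_path):
        body = "\n".join([
            _dssp_line(1, 1, "A", "G", 5),
            f"{2:5d}     " + "   !" + " " * 30,
            _dssp_line(3, 4, "A", "B", 7),
        ])
        path = tmp_path / "x.dssp"
        path.write_text(self.HEADER + body + "\n")
        assert read_dssp(path) == [(1, "H", 5.0), (4, "E", 7.0)]

    def test_header_without_data_errors(self, tmp_path):
        path = tmp_path / "x.dssp"
        path.write_text(self.HEADER)
        with pytest.raises(FormatError):
            read_dssp(path)


class TestReadScoreTable:
    def test_two_rows(self, tmp_path):
        path = tmp_path / "t.scores"
        path.write_text("model gdt_ts\nm1 27.02\nm2 64.8\n")
        table = read_score_table(path)
        assert table.gdt_ts("m1") == pytest.approx(27.02)
        assert table.gdt_ts("m2") == pytest.approx(64.8)

    def test_unit_scale_normalised_to_percent(self, tmp_path):
        path = tmp_path / "t.scores"
        path.write_text("model gdt_ts tm_score\nm1 0.648 0.55\n")
        table = read_score_table(path)
        assert table.gdt_ts("m1") == pytest.approx(64.8)
        assert table.tm_score("m1") == pytest.approx(0.55)

    def test_missing_gdt_column_errors(self, tmp_path):
        path = tmp_path / "t.scores"
        path.write_text("model other\nm1 5\n")
        with pytest.raises(FormatError):
            read_score_table(path)
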