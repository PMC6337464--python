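"""Unit tests of the fixed-width section parser."""

import gzip

import numpy as np
import pytest

from pdblake import (
    CompressionError,
    FixtureSpec,
    MalformedLineError,
    SectionKind,
    derive_protein_id,
    extract_section,
    make_polypeptide,
    parse_section_line,
    read_entry_text,
    section_columns,
)
from pdblake.synth import _atom_line


class TestReadEntryText:
    def test_plain_passthrough(self, tmp_path):
        text = "HEADER    X\nEND\n"
        p = tmp_path / "a.ent"
        p.write_text(text)
        assert read_entry_text(p) == text

    def test_gzip_roundtrip_by_magic_not_extension(self, tmp_path):
        text = make_polypeptide(FixtureSpec(), 0)
        p = tmp_path / "a.ent"  # deliberately no .gz suffix
        p.write_bytes(gzip.compress(text.encode("latin-1")))
        assert read_entry_text(p) == text

    def test_truncated_gzip_raises(self, tmp_path):
        blob = gzip.compress(b"HEADER\nEND\n" * 50)
        p = tmp_path / "a.ent.gz"
        p.write_bytes(blob[: len(blob) // 2])
        with pytest.raises(CompressionError):
            read_entry_text(p)


class TestDeriveProteinId:
    def test_header_idcode_uppercased(self):
        line = "HEADER    " + "X".ljust(40) + "01-JAN-00" + "   1abc"
        assert derive_protein_id(line + "\nEND\n", "fb") == "1ABC"

    def test_fallback_when_no_header(self):
        assert derive_protein_id("ATOM ...\nEND\n", "pdb0001") == "pdb0001"

    def test_header_wins_over_fallback(self):
        text = make_polypeptide(FixtureSpec(), 7)
        assert derive_protein_id(text, "fb") == "0007"


class TestParseSectionLine:
    def test_atom_roundtrip_against_fixture_writer(self):
        line = _atom_line("ATOM", 1, "CA", "ALA", "A", 1,
                          np.array([0.0, 0.0, 0.0]), "C")
        row = parse_section_line(line, SectionKind.ATOM, ("1ABC", 1))
        assert (row.serial, row.atomName, row.resName, row.chainId,
                row.resSeq) == (1, "CA", "ALA", "A", 1)
        assert (row.x, row.y, row.z) == (0.0, 0.0, 0.0)
        assert row.proteinId == "1ABC" and row.modelId == 1
        assert row.recordName == "ATOM"

    def test_atom_roundtrip_arbitrary_values(self):
        line = _atom_line("HETATM", 9999, "O", "HOH", "W", 321,
                          np.array([-123.456, 0.001, 9876.5]), "O")
        row = parse_section_line(line, SectionKind.HETATM, ("XXXX", 3))
        assert row.recordName == "HETATM"
        assert (row.serial, row.resSeq, row.modelId) == (9999, 321, 3)
        assert (row.x, row.y, row.z) == (-123.456, 0.001, 9876.5)
        assert row.occupancy == 1.0 and row.tempFactor == 0.0

    def test_seqres_padding_contract(self):
        names = "ALA GLY SER THR VAL"
        line = f"SEQRES   1 A    5  {names}"
        row = parse_section_line(line, SectionKind.SEQRES, ("1ABC", 1))
        filled = [getattr(row, f"resName{i}") for i in range(1, 6)]
        empty = [getattr(row, f"resName{i}") for i in range(6, 14)]
        assert filled == ["ALA", "GLY", "SER", "THR", "VAL"]
        assert empty == [""] * 8
        assert row.numRes == 5 and row.serNum == 1 and row.chainId == "A"

    def test_truncated_atom_line_raises_with_line_number(self):
        line = _atom_line("ATOM", 1, "CA", "ALA", "A", 1,
                          np.zeros(3), "C")[:30]
        with pytest.raises(MalformedLineError) as err:
            parse_section_line(line, SectionKind.ATOM, ("X", 1), line_number=12)
        assert err.value.line_number == 12
        assert "12" in str(err.value)

    def test_garbage_in_numeric_column_raises(self):
        good = _atom_line("ATOM", 1, "CA", "ALA", "A", 1, np.zeros(3), "C")
        bad = good[:30] + "  xx.yyy" + good[38:]
        with pytest.raises(MalformedLineError):
            parse_section_line(bad, SectionKind.ATOM, ("X", 1))


class TestExtractSection:
    def test_record_name_filter_atom_vs_hetatm(self):
        text = make_polypeptide(FixtureSpec(n_residues=2), 0)
        atoms = extract_section(text, "atom")
        het = extract_section(text, "hetatm")
        assert set(atoms["recordName"]) == {"ATOM"}
        assert len(atoms) == 6  # N, CA, C per residue
        assert len(het) == 1 and het.loc[0, "resName"] == "HOH"

    def test_model_context_tracking(self):
        text = make_polypeptide(FixtureSpec(n_residues=3, n_models=2), 0)
        atoms = extract_section(text, "atom")
        assert sorted(atoms["modelId"].unique()) == [1, 2]
        assert (atoms.groupby("modelId").size() == 9).all()

    def test_modelid_defaults_to_one_without_model_records(self):
        text = make_polypeptide(FixtureSpec(n_residues=3), 0)
        atoms = extract_section(text, "atom")
        assert set(atoms["modelId"]) == {1}

    def test_empty_entry_keeps_schema(self):
        df = extract_section("HEADER    X\nEND\n", "sheet")
        assert len(df) == 0
        assert list(df.columns) == section_columns("sheet")

    def test_rows_follow_file_order(self):
        text = make_polypeptide(FixtureSpec(n_residues=20), 0)
        atoms = extract_section(text, "atom")
        assert atoms["serial"].is_monotonic_increasing

    def test_lenient_mode_skips_and_counts(self):
        text = make_polypeptide(FixtureSpec(n_residues=4), 0)
        lines = text.splitlines()
        idx = next(i for i, l in enumerate(lines) if l.startswith("ATOM"))
        lines[idx] = lines[idx][:30]  # truncate one coordinate record
        broken = "\n".join(lines) + "\n"
        with pytest.raises(MalformedLineError):
            extract_section(broken, "atom", strict=True)
        df = extract_section(broken, "atom", strict=False)
        assert len(df) == 11
        assert df.attrs["malformedLinesSkipped"] == 1

    def test_gz_invariance(self, tmp_path):
        text = make_polypeptide(FixtureSpec(n_residues=5), 0)
        plain = tmp_path / "a.ent"
        plain.write_text(text)
        gzed = tmp_path / "a.ent.gz"
        gzed.write_bytes(gzip.compress(text.encode("latin-1")))
        a = extract_section(read_entry_text(plain), "atom")
        b = extract_section(read_entry_text(gzed), "atom")
        assert a.equals(b)

    def test_helix_and_sheet_records_parse(self):
        helix = ("HELIX    1  H1 ALA A    1  GLY A   10  1"
                 + " " * 30 + " " + "   10")
        sheet = ("SHEET    1   A 2 ILE A  20  VAL A  25  0")
        entry = "HEADER    " + "X".ljust(40) + "01-JAN-00" + "   1ABC\n" \
            + helix + "\n" + sheet + "\nEND\n"
        h = extract_section(entry, "helix")
        s = extract_section(entry, "sheet")
        assert h.loc[0, "serNum"] == 1 and h.loc[0, "initResName"] == "ALA"
        assert h.loc[0, "endSeqNum"] == 10 and h.loc[0, "helixClass"] == 1
        assert h.loc[0, "length"] == 10
        assert s.loc[0, "strand"] == 1 and s.loc[0, "sense"] == 0
        assert s.loc[0, "numStrands"] == 2 and s.loc[0, "endSeqNum"] == 25


class TestSeqresInvariant:
    def test_residue_count_matches_numres(self, corpus_factory):
        paths, spec = corpus_factory(n_entries=2, n_residues=30, n_chains=2)
        for p in paths:
            df = extract_section(read_entry_text(p), "seqres")
            name_cols = [f"resName{i}" for i in range(1, 14)]
            for chain, g in df.groupby("chainId"):
                total = (g[name_cols] != "").to_numpy().sum()
                assert total == g["numRes"].iloc[0] == spec.n_residues


class TestIndependentParserOracle:
    def test_atom_fields_match_gemmi(self, corpus_factory):
        gemmi = pytest.importorskip("gemmi")
        paths, _ = corpus_factory(n_entries=3, n_residues=15, n_chains=2,
                                  seed=11)
        for p in paths:
            ours = extract_section(read_entry_text(p), "atom")
            st = gemmi.read_structure(str(p))
            ref = [
                (a.serial, a.name, r.name, c.name, r.seqid.num,
                 a.pos.x, a.pos.y, a.pos.z)
                for m in st for c in m for r in c for a in r
                if r.het_flag == "A"
            ]
            got = list(ours[["serial", "atomName", "resName", "chainId",
                             "resSeq", "x", "y", "z"]].itertuples(index=False,
                                                                  name=None))
            assert got == ref
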