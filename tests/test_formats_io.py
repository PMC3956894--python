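"""File-format readers/writers and MSA preprocessing."""

import numpy as np
import pytest

from contactfold.formats_io import (
    Alignment,
    ParseError,
    SequenceRecord,
    _aligned_record,
    filter_msa,
    read_contacts,
    read_fasta,
    read_ss2,
    read_structure,
    write_contacts,
    write_fasta,
    write_ss2,
    write_structure,
)
from contactfold.geometry import build_chain
from contactfold.synthetic import ToySpec, make_toy


class TestContacts:
    def write(self, tmp_path, lines, name="t.rr"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_casp_rr_parse_sorted_by_ppv(self, tmp_path):
        p = self.write(tmp_path, ["3 40 0 8 0.9", "5 10 0 8 0.2"])
        cl = read_contacts(p)
        assert len(cl) == 2
        # 0-based internally, highest ppv first
        assert (cl[0].i, cl[0].j, cl[0].ppv) == (2, 39, 0.9)

    def test_short_separation_dropped(self, tmp_path):
        p = self.write(tmp_path, ["10 12 0 8 0.7"])
        assert len(read_contacts(p)) == 0

    def test_zero_ppv_excluded_strictly(self, tmp_path):
        p = self.write(tmp_path, ["3 40 0 8 0.0", "4 50 0 8 0.5"])
        assert len(read_contacts(p, min_ppv=0.0)) == 1

    def test_two_and_three_column_dialects(self, tmp_path):
        p = self.write(tmp_path, ["3 40 0.9", "5 30"])
        cl = read_contacts(p)
        assert len(cl) == 2
        assert cl[0].ppv == 1.0  # bare pair defaults to full confidence

    def test_headers_skipped(self, tmp_path):
        p = self.write(
            tmp_path,
            ["PFRMAT RR", "TARGET t1", "MODEL 1", "1 20 0 8 0.8", "END"],
        )
        assert len(read_contacts(p)) == 1

    def test_duplicate_keeps_highest_ppv(self, tmp_path):
        p = self.write(tmp_path, ["3 40 0 8 0.3", "3 40 0 8 0.8"])
        cl = read_contacts(p)
        assert len(cl) == 1
        assert cl[0].ppv == 0.8

    def test_reversed_indices_normalized(self, tmp_path):
        p = self.write(tmp_path, ["40 3 0 8 0.5"])
        cl = read_contacts(p)
        assert (cl[0].i, cl[0].j) == (2, 39)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = self.write(tmp_path, ["1 20 0 8 0.5", "oops bad line here x"])
        with pytest.raises(ParseError, match=":2"):
            read_contacts(p)

    def test_ordering_invariant_under_line_order(self, tmp_path):
        lines = ["3 40 0 8 0.9", "5 20 0 8 0.5", "2 30 0 8 0.7"]
        a = read_contacts(self.write(tmp_path, lines, "a.rr"))
        b = read_contacts(self.write(tmp_path, lines[::-1], "b.rr"))
        assert [(r.i, r.j, r.ppv) for r in a] == [(r.i, r.j, r.ppv) for r in b]

    def test_write_read_roundtrip(self, tmp_path):
        p = self.write(tmp_path, ["3 40 0 8 0.9", "5 20 0 8 0.123456"])
        cl = read_contacts(p, L=50)
        out = tmp_path / "out.rr"
        write_contacts(cl, out)
        back = read_contacts(out, L=50)
        for r1, r2 in zip(cl, back):
            assert (r1.i, r1.j) == (r2.i, r2.j)
            assert r1.ppv == pytest.approx(r2.ppv, abs=1e-6)


class TestSS2:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "t.ss2"
        p.write_text(
            "# PSIPRED VFORMAT\n\n"
            "1 M C 0.9 0.0 0.1\n2 A H 0.1 0.8 0.1\n3 L H 0.0 0.9 0.1\n"
        )
        pred = read_ss2(p)
        assert pred.states == "CHH"
        assert pred.confidences[1, 1] == pytest.approx(0.8)

    def test_empty_body_raises(self, tmp_path):
        p = tmp_path / "e.ss2"
        p.write_text("# PSIPRED VFORMAT\n\n")
        with pytest.raises(ParseError):
            read_ss2(p)

    def test_bad_triplet_renormalized_with_warning(self, tmp_path, caplog):
        p = tmp_path / "r.ss2"
        p.write_text("1 M H 0.25 0.2 0.05\n")
        with caplog.at_level("WARNING", logger="contactfold"):
            pred = read_ss2(p)
        assert "renormaliz" in caplog.text
        assert pred.confidences[0].sum() == pytest.approx(1.0)

    def test_length_mismatch_raises(self, tmp_path):
        p = tmp_path / "m.ss2"
        p.write_text("1 M H 0.1 0.8 0.1\n")
        with pytest.raises(ParseError):
            read_ss2(p, sequence="MA")

    def test_write_read_roundtrip(self, tmp_path, toy60):
        _, record, pred = toy60
        p = tmp_path / "w.ss2"
        write_ss2(pred, record.sequence, p)
        back = read_ss2(p, sequence=record.sequence)
        assert back.states == pred.states
        assert np.allclose(back.confidences, pred.confidences, atol=5e-3)


class TestPDB:
    def test_roundtrip_ca_to_milliangstrom(self, tmp_path, toy60):
        native, _, _ = toy60
        p = tmp_path / "n.pdb"
        write_structure(native, p)
        back = read_structure(p)
        assert back.sequence == native.sequence
        assert np.allclose(back.ca, native.ca, atol=1e-3)
        assert back.segments == [(0, len(native))]

    def test_glycine_virtual_cb(self, tmp_path):
        conf = build_chain("AGA", [[-57, -47, 180]] * 3)
        p = tmp_path / "g.pdb"
        write_structure(conf, p)
        back = read_structure(p)
        # no CB atom is written for glycine; reader synthesises the ideal one
        assert np.allclose(back.coords[1, 4], conf.coords[1, 4], atol=2e-3)

    def test_chain_selection(self, tmp_path):
        a = build_chain("AAAA", [[-57, -47, 180]] * 4)
        b = build_chain("VV", [[-139, 135, 180]] * 2)
        p = tmp_path / "two.pdb"
        with open(p, "w") as fh:
            from contactfold.formats_io import _pdb_atom_lines

            la, serial = _pdb_atom_lines(a, chain="A")
            lb, _ = _pdb_atom_lines(b, serial_start=serial, chain="B")
            fh.write("\n".join(la + lb) + "\nEND\n")
        only_b = read_structure(p, chain="B")
        assert only_b.sequence == "VV"

    def test_no_residues_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ParseError):
            read_structure(p)

    def test_chain_break_recorded_as_segments(self, tmp_path, toy60):
        native, _, _ = toy60
        p = tmp_path / "b.pdb"
        shifted = native.copy()
        shifted.coords[30:] += 60.0  # open a >4.5 A CA-CA gap
        write_structure(shifted, p)
        back = read_structure(p)
        assert back.segments == [(0, 30), (30, len(native))]

    def test_altloc_b_ignored(self, tmp_path):
        conf = build_chain("AA", [[-57, -47, 180]] * 2)
        p = tmp_path / "alt.pdb"
        from contactfold.formats_io import _pdb_atom_lines

        lines, _ = _pdb_atom_lines(conf)
        # interleave a B altloc copy of each atom, as deposited files do
        interleaved = []
        for ln in lines:
            interleaved.append(ln[:16] + "A" + ln[17:])
            shadow = ln[:16] + "B" + ln[17:]
            # displace the alternate location so picking it would be visible
            x = float(shadow[30:38]) + 5.0
            interleaved.append(shadow[:30] + f"{x:8.3f}" + shadow[38:])
        p.write_text("\n".join(interleaved) + "\nEND\n")
        back = read_structure(p)
        assert back.sequence == "AA"
        assert np.allclose(back.ca, conf.ca, atol=1e-3)


class TestFasta:
    def test_roundtrip(self, tmp_path):
        rec = SequenceRecord("t", "ACDEFGHIKLMNPQRSTVWYX")
        p = tmp_path / "t.fasta"
        write_fasta(rec, p)
        assert read_fasta(p) == rec

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError):
            SequenceRecord("bad", "ACDB")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            SequenceRecord("e", "")


class TestFilterMSA:
    def make_aln(self, rows):
        return Alignment([_aligned_record(f"r{i}", s) for i, s in enumerate(rows)])

    def test_duplicates_removed(self):
        target = SequenceRecord("q", "ACDEFGHIKL")
        aln = self.make_aln(["ACDEFGHIKL", "ACDEFGHIKL", "ACDEFGHIKL"])
        assert len(filter_msa(aln, target)) == 1

    def test_low_identity_rows_removed(self):
        target = SequenceRecord("q", "ACDEFGHIKL")
        aln = self.make_aln(["ACDEFGHIKL", "AC--------", "ACDEF-----"])
        out = filter_msa(aln, target, min_identity=0.30)
        # 2/10 matches < 0.3 -> dropped; 5/10 >= 0.3 -> kept
        assert [r.sequence for r in out.rows] == ["ACDEFGHIKL", "ACDEF-----"]

    def test_query_gap_columns_deleted(self):
        target = SequenceRecord("q", "ACDEFGHIK")
        aln = self.make_aln(["ACD-EFGHIK", "ACDWEFGHIK"])
        out = filter_msa(aln, target)
        assert out.query.sequence == "ACDEFGHIK"
        assert out.rows[1].sequence == "ACDEFGHIK"
        assert "-" not in out.query.sequence

    def test_all_filtered_raises(self):
        target = SequenceRecord("q", "ACDEFGHIKL")
        aln = self.make_aln(["ACDEFGHIKL", "WWWWWWWWWW"])
        out = filter_msa(aln, target, min_identity=0.3)
        assert len(out) == 1  # only the query survives
        aln2 = self.make_aln(["ACDEFGHIKL"])
        # degenerate: a single (query) row still returns the query
        assert len(filter_msa(aln2, target)) == 1


class TestSyntheticRoundtrips:
    def test_toy_artifacts_roundtrip(self, tmp_path):
        native, record, ss_pred = make_toy(ToySpec("beta_hairpin", 30, 2))
        write_structure(native, tmp_path / "t.pdb")
        back = read_structure(tmp_path / "t.pdb")
        assert np.allclose(back.ca, native.ca, atol=1e-3)
        write_fasta(record, tmp_path / "t.fasta")
        assert read_fasta(tmp_path / "t.fasta") == record
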