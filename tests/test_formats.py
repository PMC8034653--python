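"""Format parsing: dot-bracket, CT, SAM, FASTA, PDB, tables."""

import io

import numpy as np
import pytest

from shapebench import (StructureParseError, read_ct,
                        read_dotbracket, read_fasta, read_pdb_residues,
                        read_sam, write_dotbracket)
from shapebench.formats import (ReferenceStructure, read_reactivity_table,
                                write_ct, write_fasta, write_reactivity_table,
                                write_sam)
from shapebench.synthetic import sample_structure


class TestDotBracket:
    def test_smallest_hairpin(self):
        s = read_dotbracket("GGGAAACCC\n(((...)))")
        assert s.pairs() == [(1, 9), (2, 8), (3, 7)]

    def test_all_unpaired(self):
        s = read_dotbracket("AAAAA\n.....")
        assert not s.pairs()
        assert np.all(s.pair_table == 0)

    def test_pseudoknot_layers_and_strip(self):
        text = "AAAAAAAAAAAAAA\n((..[[..))..]]"
        s = read_dotbracket(text)
        assert dict(s.pairs()) == {1: 10, 2: 9, 5: 14, 6: 13}
        stripped = read_dotbracket(text, strip_pseudoknots=True)
        assert dict(stripped.pairs()) == {1: 10, 2: 9}

    def test_header_is_optional(self):
        assert read_dotbracket(">rna1\nGC\n..").id == "rna1"
        assert read_dotbracket("GC\n..").id == "structure"

    def test_unbalanced_brackets_name_position(self):
        with pytest.raises(StructureParseError, match="position 3"):
            read_dotbracket("AAA\n..)")
        with pytest.raises(StructureParseError, match="never closed"):
            read_dotbracket("AAA\n.(.")

    def test_length_mismatch(self):
        with pytest.raises(StructureParseError, match="length"):
            read_dotbracket("AAAA\n...")

    @pytest.mark.parametrize("seed", range(8))
    def test_roundtrip_identity_pseudoknot_free(self, seed):
        s = sample_structure(60 + 10 * seed, seed)
        again = read_dotbracket(write_dotbracket(s))
        assert again.pairs() == s.pairs()
        assert again.dotbracket == s.dotbracket


class TestCt:
    def test_cross_format_identity(self, hairpin):
        ct = write_ct(hairpin)
        s = read_ct(ct)
        assert s.pairs() == hairpin.pairs()
        assert s.sequence == hairpin.sequence
        # and round-trips through dot-bracket on pseudoknot-free input
        assert read_dotbracket(write_dotbracket(s)).pairs() == hairpin.pairs()

    def test_empty_file_errors(self):
        with pytest.raises(StructureParseError):
            read_ct("")

    def test_asymmetric_pairing_errors(self):
        rows = ["5 test",
                "1 G 0 2 0 1",
                "2 G 1 3 0 2",
                "3 A 2 4 0 3",
                "4 A 3 5 0 4",
                "5 C 4 0 3 5"]  # row 5 claims 3, row 3 claims nothing
        with pytest.raises(StructureParseError, match="asymmetric"):
            read_ct("\n".join(rows))


SAM_FIXTURE = "\n".join([
    "@HD\tVN:1.6",
    "@SQ\tSN:ref\tLN:20",
    "r1\t0\tref\t1\t60\t5M\t*\t0\t0\tACGUA\tIIIII",
    "r2\t0\tref\t6\t60\t3M1D2M\t*\t0\t0\tACGAC\tIIIII",
    "r3\t4\tref\t0\t0\t*\t*\t0\t0\tACGUA\tIIIII",  # unmapped
    "r4\t0\tref\t11\t60\t2M2I3M\t*\t0\t0\tACGGUAC\tIIIIIII",
]) + "\n"


class TestSam:
    def test_fixture_parses_with_correct_starts(self):
        reads = read_sam(SAM_FIXTURE)
        assert len(reads) == 4
        assert [r.pos for r in reads] == [1, 6, 0, 11]
        assert reads[1].cigar == [("M", 3), ("D", 1), ("M", 2)]
        assert not reads[2].is_mapped

    def test_cigar_seq_mismatch_skipped(self, caplog):
        bad = SAM_FIXTURE + "r5\t0\tref\t1\t60\t10M\t*\t0\t0\tACGU\tIIII\n"
        reads = read_sam(bad)
        assert len(reads) == 4  # the malformed record is dropped, not fatal

    def test_roundtrip(self):
        reads = read_sam(SAM_FIXTURE)
        text = write_sam([r for r in reads if r.is_mapped], "ref", 20)
        again = read_sam(text)
        assert [(r.pos, r.cigar, r.seq) for r in again] == \
               [(r.pos, r.cigar, r.seq) for r in reads if r.is_mapped]


def test_fasta_roundtrip():
    text = write_fasta({"a": "ACGU", "b": "GGCC"})
    assert read_fasta(text) == {"a": "ACGU", "b": "GGCC"}
    with pytest.raises(ValueError):
        read_fasta("no fasta here\n")


def test_reactivity_table_preserves_nan():
    values = [0.1, np.nan, 2.5]
    text = write_reactivity_table([1, 2, 3], "ACG", values)
    df = read_reactivity_table(text)
    out = df["reactivity"].to_numpy()
    assert np.isnan(out[1])
    np.testing.assert_allclose(out[[0, 2]], [0.1, 2.5])


def _atom_line(serial, name, resname, chain, resnum, x, y, z, occ=1.0,
               element="C", altloc=" "):
    return (f"ATOM  {serial:>5} {name:<4}{altloc}{resname:>3} {chain}"
            f"{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2}")


class TestPdb:
    def test_single_atom_gets_table_radius(self):
        text = _atom_line(1, "C1'", "G", "A", 1, 0.0, 0.0, 0.0, element="C")
        residues = read_pdb_residues(text)
        assert len(residues) == 1 and len(residues[0].atoms) == 1
        assert residues[0].atoms[0].radius == pytest.approx(1.70)

    def test_altloc_keeps_highest_occupancy(self):
        text = "\n".join([
            _atom_line(1, "C1'", "G", "A", 1, 0.0, 0.0, 0.0, occ=0.6, altloc="A"),
            _atom_line(2, "C1'", "G", "A", 1, 5.0, 0.0, 0.0, occ=0.4, altloc="B"),
        ])
        residues = read_pdb_residues(text)
        assert len(residues[0].atoms) == 1
        assert residues[0].atoms[0].x == pytest.approx(0.0)

    def test_residues_ordered_and_waters_excluded(self):
        lines = [
            _atom_line(1, "P", "U", "B", 2, 1.0, 0.0, 0.0, element="P"),
            _atom_line(2, "P", "G", "A", 3, 2.0, 0.0, 0.0, element="P"),
            _atom_line(3, "O", "HOH", "A", 99, 9.0, 0.0, 0.0, element="O"),
            _atom_line(4, "P", "A", "A", 1, 3.0, 0.0, 0.0, element="P"),
            _atom_line(5, "P", "C", "B", 1, 4.0, 0.0, 0.0, element="P"),
            _atom_line(6, "P", "C", "A", 2, 5.0, 0.0, 0.0, element="P"),
        ]
        residues = read_pdb_residues("\n".join(lines))
        assert [(r.chain, r.resnum) for r in residues] == \
               [("A", 1), ("A", 2), ("A", 3), ("B", 1), ("B", 2)]

    def test_no_atoms_errors(self):
        with pytest.raises(ValueError):
            read_pdb_residues("REMARK nothing here\n")


def test_pair_table_symmetry_enforced():
    pt = np.zeros(10, dtype=np.int32)
    pt[1], pt[9] = 9, 2  # 1 -> 9 but 9 -> 2
    with pytest.raises(StructureParseError, match="asymmetric"):
        ReferenceStructure(id="bad", sequence="A" * 9, pair_table=pt)
    pt = np.zeros(4, dtype=np.int32)
    pt[2] = 2
    with pytest.raises(StructureParseError, match="itself"):
        ReferenceStructure(id="bad", sequence="AAA", pair_table=pt)
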