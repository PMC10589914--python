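import numpy as np
import pytest

from structkit.structio import (
    ParseError,
    Structure,
    chain_sequence,
    extract_range,
    parse_mmcif,
    parse_pdb,
    write_mmcif,
    write_pdb,
)

from conftest import max_coord_delta, same_hierarchy

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
END
"""


class TestParsePDB:
    def test_minimal_block(self):
        s = parse_pdb(MINIMAL_PDB)
        assert len(s.chains) == 1
        assert len(s.chains[0].residues) == 1
        assert len(s.chains[0].residues[0].atoms) == 5
        np.testing.assert_allclose(s.chains[0].residues[0].atoms[1].coords,
                                   [1.458, 0.0, 0.0])

    def test_helix_roundtrip(self, helix12):
        s = parse_pdb(write_pdb(Structure("h", [helix12])))
        assert len(s.chains[0].residues) == 12
        assert s.chains[0].chain_type == "protein"

    def test_altloc_highest_occupancy_kept(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.40  0.00           C\n"
        )
        res = parse_pdb(text).chains[0].residues[0]
        assert len(res.atoms) == 1
        assert res.atoms[0].alt_loc == "A"
        assert res.atoms[0].coords[0] == 0.0

    def test_altloc_tie_broken_alphabetically(self):
        text = (
            "ATOM      1  CA BALA A   1       5.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C\n"
        )
        res = parse_pdb(text).chains[0].residues[0]
        assert res.atoms[0].alt_loc == "A"

    def test_empty_input_raises(self):
        with pytest.raises(ParseError, match="no atoms"):
            parse_pdb("HEADER    NOTHING\nEND\n")

    def test_malformed_coordinate_names_line(self):
        bad = "ATOM      1  CA  ALA A   1       x.xxx   0.000   0.000  1.00  0.00\n"
        with pytest.raises(ParseError, match="line 1"):
            parse_pdb(bad)

    def test_multi_model_default_first(self, helix12, strand8):
        text = ("MODEL        1\n" + write_pdb(Structure("a", [helix12])).replace("END\n", "")
                + "ENDMDL\nMODEL        2\n"
                + write_pdb(Structure("b", [strand8])).replace("END\n", "") + "ENDMDL\nEND\n")
        assert len(parse_pdb(text).chains[0].residues) == 12
        assert len(parse_pdb(text, model=2).chains[0].residues) == 8
        with pytest.raises(ParseError, match="model 3"):
            parse_pdb(text, model=3)

    def test_atom_count_conserved(self, fixture_structures):
        for s in fixture_structures.values():
            text = write_pdb(s)
            n_records = sum(1 for ln in text.splitlines()
                            if ln.startswith(("ATOM  ", "HETATM")))
            assert parse_pdb(text).atom_count() == n_records


class TestWritePDB:
    def test_roundtrip_all_fixtures(self, fixture_structures):
        for s in fixture_structures.values():
            s2 = parse_pdb(write_pdb(s))
            assert same_hierarchy(s, s2)
            assert max_coord_delta(s, s2) <= 1e-3

    def test_residue_number_right_justified(self, helix12):
        from copy import deepcopy
        h = Structure("h", [deepcopy(helix12)])
        h.chains[0].residues[0].number = 9999
        line = write_pdb(h).splitlines()[0]
        assert line[22:26] == "9999"

    def test_occupancy_field(self, helix12):
        line = write_pdb(Structure("h", [helix12])).splitlines()[0]
        assert line[54:60] == "  1.00"

    def test_long_chain_id_rejected(self, helix12):
        from structkit.structio import Chain
        bad = Structure("x", [Chain(chain_id="AB", residues=helix12.residues)])
        with pytest.raises(ValueError, match="column limit"):
            write_pdb(bad)

    def test_biopython_reads_output(self, fixture_structures, tmp_path):
        """Cross-check: an independent PDB reader sees the same atoms."""
        from Bio.PDB import PDBParser
        s = fixture_structures["scaffold"]
        path = tmp_path / "scaffold.pdb"
        path.write_text(write_pdb(s))
        bio = PDBParser(QUIET=True).get_structure("s", str(path))
        bio_atoms = list(bio.get_atoms())
        assert len(bio_atoms) == s.atom_count()
        mine = [a.coords for c in s.chains for r in c.residues for a in r.atoms]
        theirs = [a.coord for a in bio_atoms]
        np.testing.assert_allclose(np.array(mine), np.array(theirs), atol=1e-3)


class TestParseMmcif:
    def test_hand_written_loop(self):
        text = "\n".join([
            "data_test", "loop_",
            "_atom_site.group_PDB", "_atom_site.id", "_atom_site.type_symbol",
            "_atom_site.auth_atom_id", "_atom_site.auth_comp_id",
            "_atom_site.auth_asym_id", "_atom_site.auth_seq_id",
            "_atom_site.Cartn_x", "_atom_site.Cartn_y", "_atom_site.Cartn_z",
            "ATOM 1 N N ALA A 1 0.0 0.0 0.0",
            "ATOM 2 C CA ALA A 1 1.458 0.0 0.0",
            "ATOM 3 C C ALA A 1 2.009 1.420 0.0",
        ])
        s = parse_mmcif(text)
        assert len(s.chains) == 1
        assert len(s.chains[0].residues) == 1
        assert len(s.chains[0].residues[0].atoms) == 3

    def test_format_equivalence(self, fixture_structures):
        for s in fixture_structures.values():
            from_pdb = parse_pdb(write_pdb(s))
            from_cif = parse_mmcif(write_mmcif(s))
            assert same_hierarchy(from_pdb, from_cif)
            assert max_coord_delta(from_pdb, from_cif) <= 1e-6

    def test_quoted_values_match_gemmi(self):
        """Quoted tokens with spaces parse identically to the reference
        mmCIF tokenizer."""
        import gemmi
        text = "\n".join([
            "data_q", "loop_",
            "_atom_site.group_PDB", "_atom_site.id", "_atom_site.type_symbol",
            "_atom_site.auth_atom_id", "_atom_site.auth_comp_id",
            "_atom_site.auth_asym_id", "_atom_site.auth_seq_id",
            "_atom_site.Cartn_x", "_atom_site.Cartn_y", "_atom_site.Cartn_z",
            'ATOM 1 C "C1\'" \'D A\' A 1 0.0 1.0 2.0',
            "ATOM 2 N N1 'D A' A 1 1.5 1.0 2.0",
        ])
        s = parse_mmcif(text)
        res = s.chains[0].residues[0]
        assert res.res_name == "D A"
        assert res.atoms[0].name == "C1'"
        doc = gemmi.cif.read_string(text)
        table = doc[0].find("_atom_site.", ["auth_atom_id", "auth_comp_id"])
        ref = [(gemmi.cif.as_string(row[0]), gemmi.cif.as_string(row[1])) for row in table]
        assert [(a.name, res.res_name) for a in res.atoms] == ref

    def test_missing_loop_raises(self):
        with pytest.raises(ParseError, match="_atom_site"):
            parse_mmcif("data_x\n_cell.length_a 10.0\n")

    def test_column_mismatch_names_row(self):
        text = "\n".join([
            "data_test", "loop_",
            "_atom_site.group_PDB", "_atom_site.id", "_atom_site.auth_atom_id",
            "_atom_site.auth_comp_id", "_atom_site.auth_asym_id",
            "_atom_site.auth_seq_id", "_atom_site.Cartn_x", "_atom_site.Cartn_y",
            "_atom_site.Cartn_z",
            "ATOM 1 N ALA A 1 0.0 0.0 0.0",
            "ATOM 2 CA ALA A 1 0.0 0.0",
        ])
        with pytest.raises(ParseError, match="row 2"):
            parse_mmcif(text)


class TestChainSequence:
    def test_polyala(self, helix12):
        assert chain_sequence(helix12) == "A" * 12

    def test_selenomethionine(self, helix12):
        from copy import deepcopy
        c = deepcopy(helix12)
        c.residues[3].res_name = "MSE"
        assert chain_sequence(c)[3] == "M"

    def test_dna(self):
        from structkit.fixtures import make_dna_ladder
        assert chain_sequence(make_dna_ladder(4)) == "ACGT"

    def test_hetero_chain_rejected(self):
        from structkit.structio import Atom, Chain, Residue
        c = Chain("X", [Residue(1, "", "HOH", [Atom(1, "O", "O", [0, 0, 0])])])
        with pytest.raises(ValueError, match="hetero"):
            chain_sequence(c)


class TestExtractRange:
    def test_single_residue(self, helix12):
        assert len(extract_range(helix12, 1, 1).residues) == 1

    def test_full_chain_is_identity(self, helix12):
        sub = extract_range(helix12, 1, 12)
        assert [r.id for r in sub.residues] == [r.id for r in helix12.residues]

    def test_spans_insertion_codes(self, helix12):
        from copy import deepcopy
        c = deepcopy(helix12)
        # renumber to 29, 30, 30A, 31, ... (file order preserved)
        ids = [(29, ""), (30, ""), (30, "A"), (31, "")] + [(32 + i, "") for i in range(8)]
        for r, (num, ic) in zip(c.residues, ids):
            r.number, r.insertion_code = num, ic
        sub = extract_range(c, 30, 31)
        assert [r.id for r in sub.residues] == [(30, ""), (30, "A"), (31, "")]

    def test_missing_endpoint_named(self, helix12):
        with pytest.raises(KeyError, match="99"):
            extract_range(helix12, 1, 99)

    def test_reversed_range_rejected(self, helix12):
        with pytest.raises(ValueError, match="after"):
            extract_range(helix12, 5, 2)
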