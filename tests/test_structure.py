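"""Coordinate reading, unit selection and effective-atom reduction."""

import numpy as np
import pytest

from fodm.scales import ScaleLookupError, default_scale, load_scale
from fodm.structure import (
    EffectiveStructure,
    FixtureFormatError,
    SelectionError,
    StructureError,
    UnitSelection,
    effective_atoms,
    parse_selection,
    read_fixture,
    read_structure,
    select_unit,
    write_ca_pdb,
    write_fixture,
)

from conftest import structure_from_arrays


class TestReadStructure:
    def test_reads_residues_in_file_order(self, tiny_pdb):
        chains = read_structure(tiny_pdb)
        assert set(chains) == {"A", "B"}
        assert [r.seq_id for r in chains["A"]] == [1, 2, 3]
        assert [r.aa_code for r in chains["A"]] == ["GLY", "ALA", "LEU"]

    def test_water_excluded(self, tiny_pdb):
        chains = read_structure(tiny_pdb)
        assert "W" not in chains

    def test_atoms_carried_with_coordinates(self, tiny_pdb):
        gly = read_structure(tiny_pdb)["A"][0]
        assert len(gly.atoms) == 2
        assert gly.atoms[0][2:] == (0.0, 0.0, 0.0)

    def test_altloc_keeps_highest_occupancy(self, altloc_pdb):
        ala = read_structure(altloc_pdb)["A"][0]
        assert len(ala.atoms) == 1
        assert ala.atoms[0][2] == 5.0  # the occ=0.6 B conformer

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(StructureError):
            read_structure(tmp_path / "nope.pdb")

    def test_no_amino_acids_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HETATM    1  O   HOH W   1      20.000  20.000  20.000  1.00  0.00           O\nEND\n")
        with pytest.raises(StructureError):
            read_structure(path)


class TestSelectUnit:
    def test_single_fragment(self, tiny_pdb):
        chains = read_structure(tiny_pdb)
        picked = select_unit(chains, parse_selection("A:1-2"))
        assert [r.seq_id for r in picked] == [1, 2]

    def test_cross_chain_fragments_in_listed_order(self, tiny_pdb):
        chains = read_structure(tiny_pdb)
        picked = select_unit(chains, parse_selection("B:10-11+A:2-3"))
        assert [(r.chain_id, r.seq_id) for r in picked] == [("B", 10), ("B", 11), ("A", 2), ("A", 3)]

    def test_empty_fragment_names_itself(self, tiny_pdb):
        chains = read_structure(tiny_pdb)
        with pytest.raises(SelectionError, match="A:7-9"):
            select_unit(chains, parse_selection("A:7-9"))

    def test_missing_chain_raises(self, tiny_pdb):
        chains = read_structure(tiny_pdb)
        with pytest.raises(SelectionError, match="chain 'Z'"):
            select_unit(chains, parse_selection("Z:1-2"))

    def test_idempotent_reselection(self, tiny_pdb):
        chains = read_structure(tiny_pdb)
        first = select_unit(chains, parse_selection("A:1-3"))
        again = select_unit({"A": first}, parse_selection("A:1-3"))
        assert again == first

    def test_selection_grammar_round_trip(self):
        sel = parse_selection("A:198-221+C:224-298")
        assert sel.fragments == (("A", 198, 221), ("C", 224, 298))
        assert str(sel) == "A:198-221+C:224-298"

    def test_bad_grammar_raises(self):
        with pytest.raises(SelectionError):
            parse_selection("A;1-3")

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            UnitSelection(fragments=(("A", 5, 2),))


class TestEffectiveAtoms:
    def test_single_atom_residue_is_its_position(self, tiny_pdb, scale):
        chains = read_structure(tiny_pdb)
        # LEU has a single atom at (8, 0, 0)
        eff = effective_atoms(chains["A"][2:3] + chains["A"][0:1], scale)
        assert eff.residues[0].position == (8.0, 0.0, 0.0)

    def test_mean_of_two_atoms_is_midpoint(self, tiny_pdb, scale):
        chains = read_structure(tiny_pdb)
        eff = effective_atoms(chains["A"], scale)
        assert eff.residues[0].position == (1.0, 0.0, 0.0)  # GLY atoms at 0 and 2

    def test_hydrophobicity_from_scale(self, tiny_pdb, scale):
        chains = read_structure(tiny_pdb)
        eff = effective_atoms(chains["A"], scale)
        assert eff.residues[0].hydrophobicity == scale.lookup("GLY")
        assert eff.residues[2].hydrophobicity == scale.lookup("LEU")

    def test_preserves_count_and_order(self, tiny_pdb, scale):
        chains = read_structure(tiny_pdb)
        records = select_unit(chains, parse_selection("B:10-11+A:1-3"))
        eff = effective_atoms(records, scale)
        assert eff.n_residues == len(records)
        assert [r.seq_id for r in eff.residues] == [r.seq_id for r in records]

    def test_position_invariant_under_atom_permutation(self, tiny_pdb, scale):
        chains = read_structure(tiny_pdb)
        rec = chains["A"][1]
        flipped = type(rec)(rec.chain_id, rec.seq_id, rec.insertion_code,
                            rec.aa_code, rec.atoms[::-1])
        a = effective_atoms([rec, chains["A"][0]], scale)
        b = effective_atoms([flipped, chains["A"][0]], scale)
        assert a.residues[0].position == b.residues[0].position

    def test_unknown_residue_raises_scale_error(self, scale, tiny_pdb):
        chains = read_structure(tiny_pdb)
        rec = chains["A"][0]
        weird = type(rec)(rec.chain_id, rec.seq_id, rec.insertion_code, "XXX", rec.atoms)
        with pytest.raises(ScaleLookupError):
            effective_atoms([weird, chains["A"][1]], scale)


class TestFixtureRoundTrip:
    def test_lossless_round_trip(self, micelle100, tmp_path):
        path = tmp_path / "m.txt"
        write_fixture(micelle100, path)
        back = read_fixture(path)
        assert back.unit_label == micelle100.unit_label
        np.testing.assert_allclose(back.coords, micelle100.coords, atol=5e-7)
        np.testing.assert_allclose(back.hydrophobicity, micelle100.hydrophobicity, atol=5e-7)
        assert [r.aa_code for r in back.residues] == [r.aa_code for r in micelle100.residues]

    def test_single_residue_structure_refused(self):
        with pytest.raises(ValueError, match=">= 2"):
            structure_from_arrays([[0, 0, 0]], [1.0])

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("# fodm-fixture\nA 1 ALA 0 0 0 0.5\nA two ALA 1 1 1 0.5\n")
        with pytest.raises(FixtureFormatError, match=":3"):
            read_fixture(path)

    def test_ca_pdb_export_readable(self, micelle100, tmp_path):
        path = tmp_path / "m.pdb"
        write_ca_pdb(micelle100, path)
        chains = read_structure(path)
        assert sum(len(v) for v in chains.values()) == micelle100.n_residues


class TestScales:
    def test_default_scale_covers_standard_residues_in_unit_range(self, scale):
        vals = [scale.lookup(aa) for aa in
                "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()]
        assert min(vals) == 0.0 and max(vals) == 1.0
        assert scale.cutoff == 9.0

    def test_mse_maps_to_met(self, scale):
        assert scale.lookup("MSE") == scale.lookup("MET")

    def test_tsv_round_trip(self, tmp_path, scale):
        path = tmp_path / "s.tsv"
        rows = "\n".join(f"{aa}\t{v}" for aa, v in scale.values.items())
        path.write_text("# cutoff=7.5\n" + rows + "\n")
        loaded = load_scale(path)
        assert loaded.cutoff == 7.5
        assert loaded.values == scale.values
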