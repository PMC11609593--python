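import numpy as np
import pytest

from fodm.scales import default_scale
from fodm.structure import EffectiveResidue, EffectiveStructure


def _pdb_atom(serial, name, resname, chain, resseq, x, y, z, occ=1.0, altloc=" ",
              icode=" ", element=None, record="ATOM"):
    element = element or name[0]
    return (
        f"{record:<6s}{serial:5d} {name:^4s}{altloc}{resname:<3s} {chain}{resseq:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def tiny_pdb(tmp_path):
    """Hand-written 3-residue chain A + 2-residue chain B + one water."""
    lines = [
        _pdb_atom(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0),
        _pdb_atom(2, "CA", "GLY", "A", 1, 2.0, 0.0, 0.0, element="C"),
        _pdb_atom(3, "CA", "ALA", "A", 2, 4.0, 0.0, 0.0, element="C"),
        _pdb_atom(4, "CB", "ALA", "A", 2, 4.0, 2.0, 0.0, element="C"),
        _pdb_atom(5, "CA", "LEU", "A", 3, 8.0, 0.0, 0.0, element="C"),
        _pdb_atom(6, "CA", "PHE", "B", 10, 0.0, 8.0, 0.0, element="C"),
        _pdb_atom(7, "CA", "VAL", "B", 11, 3.0, 8.0, 0.0, element="C"),
        _pdb_atom(8, "O", "HOH", "W", 1, 20.0, 20.0, 20.0, record="HETATM"),
        "END",
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """One residue whose CA has two conformers (B has higher occupancy)."""
    lines = [
        _pdb_atom(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.4, altloc="A", element="C"),
        _pdb_atom(2, "CA", "ALA", "A", 1, 5.0, 0.0, 0.0, occ=0.6, altloc="B", element="C"),
        _pdb_atom(3, "CA", "GLY", "A", 2, 1.0, 1.0, 1.0, element="C"),
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def scale():
    return default_scale()


def structure_from_arrays(points, h, chain="A", label="test"):
    """Build an EffectiveStructure straight from coordinate/H arrays."""
    points = np.asarray(points, dtype=float)
    h = np.asarray(h, dtype=float)
    residues = [
        EffectiveResidue(chain, i + 1, "ALA", tuple(map(float, p)), float(hv))
        for i, (p, hv) in enumerate(zip(points, h))
    ]
    return EffectiveStructure(residues=residues, unit_label=label)


@pytest.fixture
def micelle100():
    from fodm.synthetic import make_micelle

    return make_micelle(100, seed=0)
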