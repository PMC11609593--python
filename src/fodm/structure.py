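"""Coordinate input, unit selection and effective-atom reduction.

A *structural unit* is an ordered set of residues, possibly assembled
from fragments of several chains (the domain-swapping case).  Each
residue is reduced to a single *effective atom* — the unweighted mean of
its atom positions — carrying the residue's intrinsic hydrophobicity.
All profile computation downstream operates on these point clouds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .scales import ScaleTable, ScaleLookupError, STANDARD_AA, PARENT_RESIDUE

__all__ = [
    "ResidueRecord",
    "UnitSelection",
    "EffectiveResidue",
    "EffectiveStructure",
    "read_structure",
    "select_unit",
    "effective_atoms",
    "write_fixture",
    "read_fixture",
    "parse_selection",
]

logger = logging.getLogger(__name__)


class StructureError(ValueError):
    """Unreadable or empty coordinate input."""


class SelectionError(ValueError):
    """A selection fragment resolves to no residues or a missing chain."""


class FixtureFormatError(ValueError):
    """Malformed fixture file."""


@dataclass(frozen=True)
class ResidueRecord:
    """One residue as read from a coordinate file (author numbering)."""

    chain_id: str
    seq_id: int
    insertion_code: str
    aa_code: str
    atoms: tuple[tuple[str, str, float, float, float], ...]  # (element, name, x, y, z)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.chain_id}{self.seq_id} has no atoms")

    @property
    def is_standard(self) -> bool:
        return self.aa_code in STANDARD_AA


@dataclass(frozen=True)
class UnitSelection:
    """Multi-fragment residue selection defining a structural unit.

    Fragments are ``(chain_id, first_seq_id, last_seq_id)`` inclusive
    ranges, in the order they should appear in the unit; fragments may
    come from different chains, e.g. ``A 198-221 + C 224-298``.
    """

    fragments: tuple[tuple[str, int, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("selection has no fragments")
        for chain, lo, hi in self.fragments:
            if lo > hi:
                raise ValueError(f"fragment {chain}:{lo}-{hi} has first > last")

    def __str__(self) -> str:
        return "+".join(f"{c}:{lo}-{hi}" for c, lo, hi in self.fragments)


def parse_selection(text: str, label: str = "") -> UnitSelection:
    """Parse the selection grammar ``A:198-221+C:224-298``.

    ``chain:first-last`` per fragment, ``+`` joining fragments; a bare
    ``chain`` (no range) is not supported — ranges are always explicit.
    """
    fragments = []
    for part in text.split("+"):
        part = part.strip()
        try:
            chain, span = part.split(":")
            lo_s, hi_s = span.split("-")
            fragments.append((chain.strip(), int(lo_s), int(hi_s)))
        except ValueError as exc:
            raise SelectionError(f"cannot parse selection fragment {part!r}") from exc
    return UnitSelection(fragments=tuple(fragments), label=label or text)


@dataclass(frozen=True)
class EffectiveResidue:
    """A residue reduced to its effective atom."""

    chain_id: str
    seq_id: int
    aa_code: str
    position: tuple[float, float, float]
    hydrophobicity: float  # intrinsic H^r, unitless


@dataclass
class EffectiveStructure:
    """Ordered effective-atom representation of a structural unit.

    ``residues`` follow fragment order, then ascending sequence order
    within a fragment.  ``N >= 2`` residues with finite coordinates.
    """

    residues: list[EffectiveResidue]
    unit_label: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError(f"structural unit needs >= 2 residues, got {len(self.residues)}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite effective-atom coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) effective-atom coordinates in Å."""
        return np.array([r.position for r in self.residues], dtype=float)

    @property
    def hydrophobicity(self) -> np.ndarray:
        """(N,) intrinsic hydrophobicity H^r."""
        return np.array([r.hydrophobicity for r in self.residues], dtype=float)

    def labels(self) -> list[str]:
        return [f"{r.chain_id}{r.seq_id}" for r in self.residues]

    def subset(self, indices: list[int] | np.ndarray, label: str | None = None) -> "EffectiveStructure":
        """A fresh unit from a subset of residues (order preserved)."""
        keep = [self.residues[i] for i in indices]
        return EffectiveStructure(residues=keep, unit_label=label if label is not None else self.unit_label)


# ---------------------------------------------------------------------------
# coordinate file reading


def _best_altloc_atoms(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per atom name: highest occupancy, ties by altloc letter."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occ, -ord(atom.altloc or "A")) > (prev.occ, -ord(prev.altloc or "A")):
            by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(
    path_or_accession: str | Path,
    fmt: str = "auto",
    model_index: int = 0,
) -> dict[str, list[ResidueRecord]]:
    """Read a PDB or mmCIF file into per-chain residue lists.

    Only polymer amino-acid residues are kept (waters, ligands and
    nucleic acids are dropped).  Author numbering is preserved.  For
    multi-model files (NMR ensembles) a single model is used
    (``model_index``, default the first).

    Returns
    -------
    dict mapping chain id to the chain's residues in file order.
    """
    path = Path(path_or_accession)
    if not path.exists():
        raise StructureError(f"coordinate file not found: {path}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[min(model_index, len(st) - 1)]

    chains: dict[str, list[ResidueRecord]] = {}
    for chain in model:
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            if info is None or not info.is_amino_acid():
                continue
            code = residue.name.upper()
            if code not in STANDARD_AA and code not in PARENT_RESIDUE:
                logger.warning("excluding unmapped non-standard residue %s %s%d",
                               code, chain.name, residue.seqid.num)
                continue
            atoms = tuple(
                (a.element.name, a.name, a.pos.x, a.pos.y, a.pos.z)
                for a in _best_altloc_atoms(residue)
            )
            if not atoms:
                continue
            chains.setdefault(chain.name, []).append(
                ResidueRecord(
                    chain_id=chain.name,
                    seq_id=residue.seqid.num,
                    insertion_code=(residue.seqid.icode or "").strip(),
                    aa_code=code,
                    atoms=atoms,
                )
            )
    chains = {k: v for k, v in chains.items() if v}
    if not chains:
        raise StructureError(f"{path}: no amino-acid residues found")
    return chains


def select_unit(
    chains: dict[str, list[ResidueRecord]],
    selection: UnitSelection,
) -> list[ResidueRecord]:
    """Resolve a multi-fragment selection against per-chain residues.

    Fragments are concatenated in the order listed; within a fragment
    residues appear in ascending author ``seq_id`` (file order preserved
    for insertion-code duplicates).  A fragment resolving to nothing is
    an error naming the fragment.
    """
    out: list[ResidueRecord] = []
    for chain_id, lo, hi in selection.fragments:
        if chain_id not in chains:
            raise SelectionError(f"chain {chain_id!r} not present (fragment {chain_id}:{lo}-{hi})")
        picked = [r for r in chains[chain_id] if lo <= r.seq_id <= hi]
        if not picked:
            raise SelectionError(f"fragment {chain_id}:{lo}-{hi} selects no residues")
        picked.sort(key=lambda r: r.seq_id)  # stable: insertion codes keep file order
        out.extend(picked)
    return out


def effective_atoms(
    residues: list[ResidueRecord],
    scale: ScaleTable,
    unit_label: str = "",
) -> EffectiveStructure:
    """Reduce residues to effective atoms with intrinsic hydrophobicity.

    The effective position is the unweighted arithmetic mean of all the
    residue's atom coordinates (hydrogens included when present); ``H^r``
    comes from the scale by residue code, with non-standard residues
    mapped to their standard parent.
    """
    eff: list[EffectiveResidue] = []
    for rec in residues:
        try:
            h = scale.lookup(rec.aa_code)
        except ScaleLookupError:
            raise
        xyz = np.array([[a[2], a[3], a[4]] for a in rec.atoms], dtype=float)
        pos = xyz.mean(axis=0)
        eff.append(
            EffectiveResidue(
                chain_id=rec.chain_id,
                seq_id=rec.seq_id,
                aa_code=rec.aa_code,
                position=(float(pos[0]), float(pos[1]), float(pos[2])),
                hydrophobicity=float(h),
            )
        )
    return EffectiveStructure(residues=eff, unit_label=unit_label)


# ---------------------------------------------------------------------------
# fixture format: whitespace-delimited text, one residue per line
# columns: chain seq_id aa_code x y z H^r, with a one-line header

_FIXTURE_HEADER = "# fodm-fixture chain seq aa x y z h"


def write_fixture(structure: EffectiveStructure, path: str | Path) -> None:
    """Write an effective structure as plain text (lossless round trip)."""
    lines = [_FIXTURE_HEADER + (f" unit={structure.unit_label}" if structure.unit_label else "")]
    for r in structure.residues:
        x, y, z = r.position
        lines.append(
            f"{r.chain_id} {r.seq_id} {r.aa_code} {x:.6f} {y:.6f} {z:.6f} {r.hydrophobicity:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def is_fixture_file(path: str | Path) -> bool:
    """True if the file starts with the fixture header line."""
    try:
        with open(path) as fh:
            return fh.readline().startswith("# fodm-fixture")
    except OSError:
        return False


def read_fixture(path: str | Path) -> EffectiveStructure:
    """Read a fixture written by :func:`write_fixture`."""
    path = Path(path)
    residues: list[EffectiveResidue] = []
    unit_label = ""
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "unit=" in line:
                unit_label = line.split("unit=", 1)[1].strip()
            continue
        parts = line.split()
        if len(parts) != 7:
            raise FixtureFormatError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
        try:
            chain, seq, aa = parts[0], int(parts[1]), parts[2]
            x, y, z, h = (float(v) for v in parts[3:])
        except ValueError as exc:
            raise FixtureFormatError(f"{path}:{lineno}: {exc}") from exc
        residues.append(
            EffectiveResidue(chain_id=chain, seq_id=seq, aa_code=aa,
                             position=(x, y, z), hydrophobicity=h)
        )
    if len(residues) < 2:
        raise FixtureFormatError(f"{path}: fixture has fewer than 2 residues")
    return EffectiveStructure(residues=residues, unit_label=unit_label)


def write_ca_pdb(structure: EffectiveStructure, path: str | Path) -> None:
    """Write effective atoms as a CA-only PDB file (exercises the reader).

    Hydrophobicity is not representable in PDB; round-tripping through
    this format requires re-assigning ``H^r`` from a scale.
    """
    lines = []
    serial = 1
    for r in structure.residues:
        x, y, z = r.position
        aa = r.aa_code if r.aa_code in STANDARD_AA else "ALA"
        lines.append(
            f"ATOM  {serial:5d}  CA  {aa:<3s} {r.chain_id[:1]}{r.seq_id:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
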