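"""Intrinsic per-residue hydrophobicity scales.

A scale maps 3-letter amino-acid codes to a unitless intrinsic
hydrophobicity ``H^r >= 0`` and carries the interaction cutoff ``c`` (Å)
used by the observed-hydrophobicity computation.  The bundled default is
the Black & Mould normalized hydrophobicity scale rescaled to [0, 1];
any two-column TSV (``CODE<TAB>value``, optional ``# cutoff=...`` header
line) can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = ["ScaleTable", "load_scale", "default_scale", "STANDARD_AA"]

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: non-standard residues mapped to a standard parent for scale lookup
PARENT_RESIDUE = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine
    "PYL": "LYS",  # pyrrolysine
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "CSO": "CYS",
    "MLY": "LYS",
}

DEFAULT_CUTOFF = 9.0


class ScaleLookupError(KeyError):
    """Residue code absent from the hydrophobicity scale."""


@dataclass(frozen=True)
class ScaleTable:
    """Mapping from 3-letter residue code to intrinsic hydrophobicity.

    Parameters
    ----------
    values
        ``{aa_code: H^r}``; must cover the 20 standard residues, all
        values non-negative.
    name
        Human-readable scale identifier.
    cutoff
        Interaction cutoff ``c`` in Å (``> 0``).
    """

    values: dict[str, float] = field(repr=False)
    name: str = "custom"
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {sorted(missing)}")
        if any(v < 0 for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} has negative hydrophobicity values")
        if not self.cutoff > 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")

    def lookup(self, aa_code: str) -> float:
        """Return ``H^r`` for a residue, following non-standard parent mapping."""
        code = aa_code.upper()
        if code in self.values:
            return self.values[code]
        parent = PARENT_RESIDUE.get(code)
        if parent is not None and parent in self.values:
            return self.values[parent]
        raise ScaleLookupError(f"residue {aa_code!r} not covered by scale {self.name!r}")

    def __contains__(self, aa_code: str) -> bool:
        try:
            self.lookup(aa_code)
        except ScaleLookupError:
            return False
        return True


def load_scale(path: str | Path, name: str | None = None) -> ScaleTable:
    """Read a scale from a two-column TSV file.

    Lines starting with ``#`` are comments; a ``# cutoff=<Å>`` line sets
    the interaction cutoff (default 9.0 Å).
    """
    path = Path(path)
    values: dict[str, float] = {}
    cutoff = DEFAULT_CUTOFF
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("cutoff"):
                cutoff = float(body.split("=", 1)[1])
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'CODE value', got {raw!r}")
        values[parts[0].upper()] = float(parts[1])
    return ScaleTable(values=values, name=name or path.stem, cutoff=cutoff)


def default_scale(cutoff: float | None = None) -> ScaleTable:
    """The bundled normalized Black & Mould scale (values in [0, 1])."""
    ref = resources.files("fodm.data").joinpath("black_mould.tsv")
    with resources.as_file(ref) as path:
        table = load_scale(path, name="black_mould")
    if cutoff is not None:
        table = ScaleTable(values=table.values, name=table.name, cutoff=cutoff)
    return table
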