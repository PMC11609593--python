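"""Domain-swapping workflows.

A swapped domain is a structural unit assembled from fragments of two
(or more) chains.  These helpers assess such composed units as one body
(one Gaussian envelope over all selected residues), quantify what a
"guest" fragment contributes to the shared hydrophobic core (RD and K
with versus without it), run batches of units into status tables, and
average profiles across homologous structures sharing residue
numbering (e.g. point mutants).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .divergence import FodStatus
from .model import FodConfig, FodModel, FodResults
from .structure import (
    EffectiveStructure,
    SelectionError,
    UnitSelection,
    parse_selection,
)

__all__ = [
    "SwapAssessment",
    "assess_unit",
    "guest_contribution",
    "batch_table",
    "average_profiles",
    "select_effective",
    "load_manifest",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SwapAssessment:
    """Host-versus-combined comparison for one guest fragment.

    ``delta_rd = combined RD - host RD``: negative when the guest
    completes the shared hydrophobic core, positive when it disrupts it.
    Both statuses are computed under the same configuration.
    """

    host_status: FodStatus
    combined_status: FodStatus
    guest_fragment: UnitSelection

    @property
    def delta_rd(self) -> float:
        return self.combined_status.rd - self.host_status.rd

    @property
    def delta_k(self) -> float:
        return self.combined_status.k - self.host_status.k

    @property
    def guest_completes_core(self) -> bool:
        return self.delta_rd < 0


def select_effective(
    structure: EffectiveStructure, selection: UnitSelection
) -> EffectiveStructure:
    """Resolve a selection against an already-reduced structure."""
    out_idx: list[int] = []
    for chain, lo, hi in selection.fragments:
        idx = [
            i
            for i, r in enumerate(structure.residues)
            if r.chain_id == chain and lo <= r.seq_id <= hi
        ]
        if not idx:
            raise SelectionError(f"fragment {chain}:{lo}-{hi} selects no residues")
        idx.sort(key=lambda i: structure.residues[i].seq_id)
        out_idx.extend(idx)
    return structure.subset(out_idx, label=selection.label or str(selection))


def _resolve(
    source: str | Path | EffectiveStructure,
    selection: UnitSelection | str | None,
    config: FodConfig,
) -> FodModel:
    from .structure import is_fixture_file, read_fixture

    if isinstance(selection, str):
        selection = parse_selection(selection)
    if isinstance(source, (str, Path)) and is_fixture_file(source):
        source = read_fixture(source)
    if isinstance(source, EffectiveStructure):
        structure = source if selection is None else select_effective(source, selection)
        return FodModel(structure, config)
    return FodModel.from_file(source, selection=selection, config=config)


def assess_unit(
    source: str | Path | EffectiveStructure,
    selection: UnitSelection | str | None = None,
    config: FodConfig | None = None,
) -> FodStatus:
    """FOD status of one (possibly multi-chain) structural unit.

    The envelope is spanned over exactly the selected residues;
    fragments from different chains are treated as one body.
    """
    return _resolve(source, selection, config or FodConfig()).fit().status()


def guest_contribution(
    source: str | Path | EffectiveStructure,
    host: UnitSelection | str,
    guest: UnitSelection | str,
    config: FodConfig | None = None,
) -> SwapAssessment:
    """Contribution of a guest fragment to the host's hydrophobic core.

    Assesses the host fragments alone (fresh envelope) and the combined
    host+guest unit, both under the same configuration.  Host and guest
    must select disjoint residue sets, and the guest must be non-empty.
    """
    config = config or FodConfig()
    if isinstance(host, str):
        host = parse_selection(host, label="host")
    if isinstance(guest, str):
        guest = parse_selection(guest, label="guest")
    host_model = _resolve(source, host, config)
    guest_model = _resolve(source, guest, config)

    def keys(m: FodModel) -> set:
        return {(r.chain_id, r.seq_id) for r in m.structure.residues}

    overlap = keys(host_model) & keys(guest_model)
    if overlap:
        raise ValueError(f"host and guest selections overlap: {sorted(overlap)[:5]} ...")

    combined = UnitSelection(
        fragments=host.fragments + guest.fragments,
        label=(host.label or str(host)) + "+" + (guest.label or str(guest)),
    )
    combined_status = _resolve(source, combined, config).fit().status()
    return SwapAssessment(
        host_status=host_model.fit().status(),
        combined_status=combined_status,
        guest_fragment=guest,
    )


# ---------------------------------------------------------------------------
# batch tables


def load_manifest(path: str | Path) -> list[tuple[str, str | None, str]]:
    """Read a batch manifest (YAML list or CSV).

    Each entry carries ``path`` (coordinate or fixture file),
    ``selection`` (selection string, optional) and ``label``.
    """
    import yaml

    path = Path(path)
    entries: list[tuple[str, str | None, str]] = []
    if path.suffix.lower() in (".yml", ".yaml"):
        data = yaml.safe_load(path.read_text())
        for row in data:
            entries.append((row["path"], row.get("selection"), row.get("label", "")))
    else:
        df = pd.read_csv(path)
        for _, row in df.iterrows():
            sel = row.get("selection")
            sel = None if pd.isna(sel) else str(sel)
            entries.append((str(row["path"]), sel, str(row.get("label", ""))))
    if not entries:
        raise ValueError(f"manifest {path} is empty")
    return entries


def batch_table(
    manifest: list[tuple[str | Path | EffectiveStructure, UnitSelection | str | None, str]],
    config: FodConfig | None = None,
) -> pd.DataFrame:
    """Status table for many units: one row per (source, selection, label).

    Mirrors the familiar results-table layout: unit id, label, fragment
    string, RD to 3 decimals, K to 1 decimal.  A failing unit is
    reported as a row with the error message, without aborting the
    batch.
    """
    if not manifest:
        raise ValueError("empty manifest")
    config = config or FodConfig()
    rows = []
    for source, selection, label in manifest:
        source_name = (
            source.unit_label if isinstance(source, EffectiveStructure) else Path(str(source)).stem
        )
        frag = str(selection) if selection is not None else ""
        try:
            status = assess_unit(source, selection, config)
            rows.append(
                {
                    "id": source_name,
                    "label": label,
                    "fragments": frag,
                    "N": status.n_residues,
                    "RD": round(status.rd, 3),
                    "K": round(status.k, 1),
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 — batch rows must not abort the run
            logger.warning("unit %s (%s) failed: %s", source_name, label, exc)
            rows.append(
                {
                    "id": source_name,
                    "label": label,
                    "fragments": frag,
                    "N": pd.NA,
                    "RD": np.nan,
                    "K": np.nan,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# profile averaging across homologous structures


def average_profiles(
    results: list[FodResults],
    roles: tuple[str, ...] = ("T", "O", "M"),
) -> tuple[pd.DataFrame, float]:
    """Average profiles across structures sharing residue numbering.

    Alignment is the intersection of ``(chain_id, seq_id)`` keys across
    all units (point mutants of one protein share numbering; no sequence
    alignment is attempted).  Positions missing from some units are
    dropped with a warning.  Returns a table of per-position arithmetic
    means and population standard deviations for each requested role,
    plus the fitted K averaged across units.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 units to average")
    keysets = []
    for res in results:
        keysets.append([(r.chain_id, r.seq_id) for r in res.structure.residues])
    common = set(keysets[0])
    for ks in keysets[1:]:
        common &= set(ks)
    if not common:
        raise ValueError("units share no residue numbering")
    dropped = max(len(ks) for ks in keysets) - len(common)
    if dropped:
        logger.warning("dropping %d positions missing from some units", dropped)
    ordered = [k for k in keysets[0] if k in common]

    data: dict[str, list] = {"chain": [k[0] for k in ordered], "seq_id": [k[1] for k in ordered]}
    for role in roles:
        stacked = []
        for res, ks in zip(results, keysets):
            profile = {"T": res.t, "O": res.o, "M": res.m}[role]
            index = {k: i for i, k in enumerate(ks)}
            stacked.append([profile.values[index[k]] for k in ordered])
        arr = np.array(stacked)
        data[f"{role}_mean"] = arr.mean(axis=0)
        data[f"{role}_std"] = arr.std(axis=0)  # population std (divide by n)
    mean_k = float(np.mean([res.k for res in results]))
    return pd.DataFrame(data), mean_k
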