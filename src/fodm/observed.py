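"""Observed hydrophobicity profile O from pairwise interactions.

The observed hydrophobicity collected by residue *i* is the sum over
its neighbours *j* (within the cutoff ``c``) of the summed intrinsic
hydrophobicities ``H_i^r + H_j^r`` weighted by a smooth polynomial decay
of the inter-effective-atom distance.  Distances are measured between
effective atoms, consistent with the single-point residue
representation.
"""

from __future__ import annotations

import numpy as np

from .envelope import Profile
from .structure import EffectiveStructure
from .scales import ScaleTable

__all__ = ["interaction_weight", "o_profile", "DegenerateProfileError"]


class DegenerateProfileError(ValueError):
    """The unit has no hydrophobic interactions (all-zero O profile)."""


def interaction_weight(r, c: float):
    """Distance weight of a hydrophobic contact, in [0, 1].

    For ``r <= c``:  ``1 - (1/2)(7x^2 - 9x^4 + 5x^6 - x^8)`` with
    ``x = r/c``; zero beyond the cutoff.  Continuous at ``r = c``
    (the bracket equals 2 there).  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    if not c > 0:
        raise ValueError("cutoff must be positive")
    x2 = (r / c) ** 2
    poly = 1.0 - 0.5 * (7 * x2 - 9 * x2**2 + 5 * x2**3 - x2**4)
    w = np.where(r <= c, poly, 0.0)
    return float(w) if w.ndim == 0 else w


def o_profile(
    structure: EffectiveStructure,
    scale: ScaleTable | None = None,
    cutoff: float | None = None,
    include_self: bool = False,
) -> Profile:
    """Observed profile from inter-residue hydrophobic interactions.

    ``O_i = sum_{j != i} (H_i^r + H_j^r) * w(r_ij, c)`` normalized over
    the unit.  ``H^r`` values are taken from the structure's effective
    residues (already assigned from a scale).  The cutoff comes from
    ``cutoff`` if given, else from ``scale``, else 9.0 Å.

    ``include_self`` adds the ``j = i`` self term (weight 1,
    contribution ``2 H_i^r``); the default is the inter-residue-only
    sum.

    Raises
    ------
    DegenerateProfileError
        if every pairwise interaction is zero (no residues within the
        cutoff, or all hydrophobicities zero).
    """
    if cutoff is not None:
        c = cutoff
    elif scale is not None:
        c = scale.cutoff
    else:
        c = 9.0
    coords = structure.coords
    h = structure.hydrophobicity
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    w = interaction_weight(dist, c)
    if not include_self:
        np.fill_diagonal(w, 0.0)
    pair_h = h[:, None] + h[None, :]
    o = (pair_h * w).sum(axis=1)
    total = o.sum()
    if total <= 0:
        raise DegenerateProfileError(
            f"unit {structure.unit_label!r}: no hydrophobic interactions within {c} Å"
        )
    return Profile(values=o / total, role="O", unit_label=structure.unit_label)
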