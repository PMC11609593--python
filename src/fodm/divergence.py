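"""Kullback–Leibler comparison of hydrophobicity profiles and the RD statistic.

RD (relative distance) locates the observed distribution O between the
theoretical micelle-like distribution T and the structureless uniform
distribution R:

    RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R))

RD < 0.5 indicates a hydrophobic core (O closer to T); RD > 0.5 its
absence.  Divergences use base-2 logarithms and are reported in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from enum import Enum

import numpy as np

from .envelope import Profile

__all__ = [
    "kl_divergence",
    "r_profile",
    "rd",
    "residue_status",
    "ResidueStatus",
    "FodStatus",
]


class DivergenceUndefinedError(ValueError):
    """P has mass where the reference Q has none."""


def kl_divergence(p: Profile | np.ndarray, q: Profile | np.ndarray) -> float:
    """D_KL(P|Q) = sum_i P_i log2(P_i / Q_i), in bits.

    Zero P terms contribute nothing (0 * log 0 = 0); a positive P term
    over a zero Q term is undefined and raises.
    """
    pv = p.values if isinstance(p, Profile) else np.asarray(p, dtype=float)
    qv = q.values if isinstance(q, Profile) else np.asarray(q, dtype=float)
    if pv.shape != qv.shape:
        raise ValueError(f"profile lengths differ: {pv.shape} vs {qv.shape}")
    support = pv > 0
    if np.any(qv[support] <= 0):
        raise DivergenceUndefinedError("P has mass where Q is zero")
    terms = pv[support] * np.log2(pv[support] / qv[support])
    return float(terms.sum())


def r_profile(n: int, unit_label: str = "") -> Profile:
    """Uniform reference distribution: every residue 1/n."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    return Profile(values=np.full(n, 1.0 / n), role="R", unit_label=unit_label)


def rd(o: Profile, t: Profile) -> float:
    """Relative distance of O between T and the uniform reference R.

    Returns 0 (with a warning) in the degenerate case where O equals
    both references (both divergences zero).
    """
    d_ot = kl_divergence(o, t)
    d_or = kl_divergence(o, r_profile(len(o)))
    denom = d_ot + d_or
    if denom == 0:
        warnings.warn("O matches both T and R exactly; RD defined as 0", stacklevel=2)
        return 0.0
    return d_ot / denom


class ResidueStatus(str, Enum):
    EXCESS = "excess"
    DEFICIENCY = "deficiency"
    MATCHED = "matched"


def residue_status(
    o: Profile, t: Profile, tau: float = 0.0
) -> tuple[list[ResidueStatus], np.ndarray]:
    """Per-residue hydrophobicity excess/deficiency relative to T.

    A residue is ``excess`` when ``O_i - T_i > tau`` (a candidate
    protein–protein interface), ``deficiency`` when ``O_i - T_i < -tau``
    (a candidate ligand-binding cavity), else ``matched``.  Returns the
    status list and the signed magnitudes ``O_i - T_i`` (which sum to 0
    over the unit, both profiles being normalized).
    """
    if len(o) != len(t):
        raise ValueError("profiles differ in length")
    delta = o.values - t.values
    statuses = [
        ResidueStatus.EXCESS if d > tau else ResidueStatus.DEFICIENCY if d < -tau else ResidueStatus.MATCHED
        for d in delta
    ]
    return statuses, delta


@dataclass(frozen=True)
class FodStatus:
    """RD / K summary of one structural unit.

    Attributes
    ----------
    unit_label : str
        Label of the assessed unit.
    n_residues : int
        Number of residues N.
    d_kl_ot, d_kl_or : float
        D_KL(O|T) and D_KL(O|R), bits.
    rd : float
        Relative distance, in [0, 1].
    k : float
        Fitted environment parameter (>= 0); 0 means pure aqueous
        micelle-like folding.
    d_kl_om : float
        D_KL(O|M) at the fitted K, bits.
    """

    unit_label: str
    n_residues: int
    d_kl_ot: float
    d_kl_or: float
    rd: float
    k: float
    d_kl_om: float

    def to_dict(self) -> dict:
        return asdict(self)

    def __str__(self) -> str:
        return (
            f"FodStatus({self.unit_label or 'unit'}: N={self.n_residues}, "
            f"RD={self.rd:.3f}, K={self.k:.1f})"
        )
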