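"""Environment-modified distribution M and the K parameter.

Membrane-like (non-polar) environments invert the micelle pattern:
hydrophobic residues are exposed at the surface.  The modified reference
blends the theoretical distribution T with its complement
``T_MAX - T_i``:

    M_i(K) ∝ T_i + K (T_MAX - T_i),   normalized over the unit,

where ``T_MAX`` is the maximum of the (normalized) T values in the
analysed unit.  K = 0 recovers T; K = 1 makes M uniform; larger K tips
the distribution towards the inverted, membrane-like pattern.  The
fitted K — the value minimizing D_KL(O|M(K)) — measures the degree of
contribution of an environment different from polar water.
"""

from __future__ import annotations

import numpy as np

from .divergence import kl_divergence
from .envelope import Profile

__all__ = ["m_profile", "fit_k"]

DEFAULT_K_MAX = 10.0
DEFAULT_K_STEP = 0.1
REFINE_STEP = 0.01


def m_profile(t: Profile, k: float) -> Profile:
    """Modified distribution M(T, K), normalized.

    ``K = 0`` returns T exactly; for uniform T the complement vanishes
    and M stays uniform for every K.
    """
    if k < 0:
        raise ValueError(f"K must be non-negative, got {k}")
    tv = t.values
    m = tv + k * (tv.max() - tv)
    total = m.sum()
    if total <= 0:
        # only possible for the degenerate single-point T; guard anyway
        raise ValueError("M profile sums to zero")
    return Profile(values=m / total, role="M", unit_label=t.unit_label)


def _scan(o: Profile, t: Profile, ks: np.ndarray) -> tuple[float, float]:
    best_k, best_d = 0.0, np.inf
    for k in ks:
        d = kl_divergence(o, m_profile(t, float(k)))
        if d < best_d - 1e-15:  # ties (within fp noise) keep the smaller K
            best_k, best_d = float(k), d
    return best_k, best_d


def fit_k(
    o: Profile,
    t: Profile,
    k_max: float = DEFAULT_K_MAX,
    k_step: float = DEFAULT_K_STEP,
) -> tuple[float, float]:
    """Grid-fit the environment parameter K.

    Coarse scan of ``[0, k_max]`` at ``k_step``, refined at 0.01
    resolution in the bracket around the coarse minimum.  Ties break
    toward smaller K.  Returns ``(K*, D_KL(O|M(K*)))``.
    """
    if len(o) != len(t):
        raise ValueError("profiles differ in length")
    coarse = np.round(np.arange(0.0, k_max + k_step / 2, k_step), 10)
    k0, d0 = _scan(o, t, coarse)
    lo = max(0.0, k0 - k_step)
    hi = min(k_max, k0 + k_step)
    fine = np.round(np.arange(lo, hi + REFINE_STEP / 2, REFINE_STEP), 10)
    k1, d1 = _scan(o, t, fine)
    if d1 < d0 or (d1 == d0 and k1 < k0):
        return k1, d1
    return k0, d0
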