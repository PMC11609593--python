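"""Synthetic effective-atom fixtures with controlled FOD statistics.

These generators build point clouds whose observed hydrophobicity
profile is steered towards a chosen reference: the theoretical Gaussian
profile T (an ideal micelle, RD near 0), the uniform profile R (no core,
RD near 1), or the environment-modified profile M(K) for a chosen K
(parameter-recovery experiments).  Geometry is a seeded Gaussian cloud
or a near-regular lattice — no attempt is made at realistic protein
geometry; what is controlled is the hydrophobicity statistics the
pipeline sees.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

import numpy as np

from .envelope import fit_envelope, t_profile
from .modified import m_profile
from .observed import interaction_weight
from .scales import default_scale
from .structure import EffectiveResidue, EffectiveStructure, UnitSelection

__all__ = ["make_micelle", "make_uniform", "make_modified", "make_swapped_pair"]

DEFAULT_SIGMAS = (8.0, 8.0, 8.0)  # Å — a compact single-domain-sized cloud


def _nearest_aa(h: float, scale_values: list[tuple[str, float]]) -> str:
    """Residue code whose scale value is closest to h (cosmetic labelling)."""
    return min(scale_values, key=lambda kv: abs(kv[1] - h))[0]


def _build(points: np.ndarray, h: np.ndarray, label: str, chain: str = "A",
           start: int = 1) -> EffectiveStructure:
    scale_values = sorted(default_scale().values.items())
    residues = [
        EffectiveResidue(
            chain_id=chain,
            seq_id=start + i,
            aa_code=_nearest_aa(float(h[i]), scale_values),
            position=(float(p[0]), float(p[1]), float(p[2])),
            hydrophobicity=float(h[i]),
        )
        for i, p in enumerate(points)
    ]
    return EffectiveStructure(residues=residues, unit_label=label)


def _weight_matrix(points: np.ndarray, cutoff: float) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    w = interaction_weight(dist, cutoff)
    np.fill_diagonal(w, 0.0)
    return w


def _calibrate_h(points: np.ndarray, target: np.ndarray, cutoff: float) -> np.ndarray:
    """Hydrophobicity assignment whose observed profile matches ``target``.

    The (unnormalized) observed profile is linear in the assignment:
    ``O = diag(S) H + W H`` with ``W`` the pairwise weight matrix and
    ``S`` its row sums, so the assignment is the non-negative
    least-squares solution of ``(W + diag(S)) H = target`` (profiles are
    scale-free, so the overall magnitude of H is arbitrary).
    """
    from scipy.optimize import nnls

    w = _weight_matrix(points, cutoff)
    a = w + np.diag(w.sum(axis=1))
    h, _ = nnls(a, target)
    h = np.clip(h, 1e-9, None)  # keep every residue weakly interacting
    # rescale into (0, 1] — cosmetic, the profiles are scale-free
    return h / h.max()


def make_micelle(
    n: int = 100,
    seed: int = 0,
    sigmas: tuple[float, float, float] = DEFAULT_SIGMAS,
) -> EffectiveStructure:
    """An ideal micelle-like unit: observed profile tracks T (RD → 0).

    ``n`` points are sampled from the centred 3D Gaussian with the given
    sigmas; each point's intrinsic hydrophobicity is proportional to its
    own theoretical value T, rescaled to [0, 1] — core points high,
    shell points low — so the pairwise-interaction profile O follows T.
    """
    if n < 10:
        raise ValueError(f"need n >= 10, got {n}")
    rng = np.random.default_rng(seed)
    points = rng.normal(0.0, np.asarray(sigmas, dtype=float), size=(n, 3))
    tmp = _build(points, np.ones(n), "tmp")
    t = t_profile(fit_envelope(tmp), tmp).values
    h = (t - t.min()) / (t.max() - t.min())
    h = np.clip(h, 1e-6, None)  # keep every residue weakly interacting
    return _build(points, h, f"micelle-n{n}-s{seed}")


def make_uniform(n: int = 125, seed: int = 0, cutoff: float | None = None) -> EffectiveStructure:
    """A core-less unit: constant hydrophobicity on a compact lattice.

    Points sit on a near-regular cubic lattice whose total extent stays
    well inside the interaction cutoff, so every residue interacts with
    every other at near-unit weight and the observed profile is close to
    uniform (O ≈ R) while T remains strongly peaked: RD → 1.  A small
    seeded jitter (1% of the spacing) makes distinct seeds give distinct
    fixtures without disturbing the statistics.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    c = cutoff if cutoff is not None else default_scale().cutoff
    side = int(np.ceil(n ** (1 / 3)))
    # whole lattice diagonal kept at <= 25% of the cutoff so every pair
    # interacts at near-unit weight
    spacing = 0.25 * c / max((side - 1) * np.sqrt(3.0), 1.0)
    grid = np.arange(side, dtype=float) * spacing
    pts = np.array([(x, y, z) for x in grid for y in grid for z in grid])[:n]
    rng = np.random.default_rng(seed)
    pts = pts + rng.normal(0.0, 0.01 * spacing, size=pts.shape)
    h = np.full(n, 0.5)
    return _build(pts, h, f"uniform-n{n}-s{seed}")


MODIFIED_SIGMAS = (5.0, 5.0, 5.0)  # Å — dense enough for exact O calibration


def make_modified(
    n: int = 200,
    seed: int = 0,
    k_true: float = 1.0,
    sigmas: tuple[float, float, float] = MODIFIED_SIGMAS,
    cutoff: float | None = None,
) -> tuple[EffectiveStructure, float]:
    """A unit whose observed profile follows M(T, k_true).

    Geometry as :func:`make_micelle`; hydrophobicities are calibrated so
    the observed profile approximates the environment-modified reference
    at ``k_true``.  Used for K-recovery experiments; ``k_true = 0``
    reduces to the micelle construction.
    """
    if n < 10:
        raise ValueError(f"need n >= 10, got {n}")
    if k_true < 0:
        raise ValueError(f"k_true must be >= 0, got {k_true}")
    rng = np.random.default_rng(seed)
    points = rng.normal(0.0, np.asarray(sigmas, dtype=float), size=(n, 3))
    c = cutoff if cutoff is not None else default_scale().cutoff
    tmp = _build(points, np.ones(n), "tmp")
    t = t_profile(fit_envelope(tmp), tmp)
    target = m_profile(t, k_true).values
    h = _calibrate_h(points, target, c)
    return _build(points, h, f"modified-n{n}-s{seed}-k{k_true}"), k_true


def make_swapped_pair(
    n: int = 120,
    seed: int = 0,
    complete: bool = True,
    sigmas: tuple[float, float, float] = DEFAULT_SIGMAS,
) -> tuple[UnitSelection, UnitSelection, EffectiveStructure]:
    """A two-chain unit mimicking a domain-swapped composition.

    One micelle-like cloud is split spatially into a host half (chain A)
    and a guest half (chain B).  With ``complete=True`` the guest
    carries the hydrophobicities that complete the joint core, so the
    combined unit scores better (lower RD) than the host alone; with
    ``complete=False`` the guest's hydrophobicities are inverted
    (polar core, hydrophobic surface) and the combined unit scores no
    better than the host alone.

    Returns ``(host_selection, guest_selection, structure)``; the
    selections are disjoint by construction (different chain ids).
    """
    if n < 20:
        raise ValueError(f"need n >= 20, got {n}")
    rng = np.random.default_rng(seed)
    points = rng.normal(0.0, np.asarray(sigmas, dtype=float), size=(n, 3))
    tmp = _build(points, np.ones(n), "tmp")
    t = t_profile(fit_envelope(tmp), tmp).values
    h = np.clip((t - t.min()) / (t.max() - t.min()), 1e-6, None)
    order = np.argsort(points[:, 0])  # spatial split: host is the low-x half
    host_idx, guest_idx = order[: n // 2], order[n // 2 :]
    if not complete:
        h = h.copy()
        h[guest_idx] = h.max() - h[guest_idx]
    scale_values = sorted(default_scale().values.items())
    residues = []
    for new_seq, i in enumerate(host_idx, start=1):
        residues.append(EffectiveResidue("A", new_seq, _nearest_aa(float(h[i]), scale_values),
                                         tuple(float(v) for v in points[i]), float(h[i])))
    for new_seq, i in enumerate(guest_idx, start=1):
        residues.append(EffectiveResidue("B", new_seq, _nearest_aa(float(h[i]), scale_values),
                                         tuple(float(v) for v in points[i]), float(h[i])))
    structure = EffectiveStructure(
        residues=residues, unit_label=f"swapped-n{n}-s{seed}-{'complete' if complete else 'broken'}"
    )
    host = UnitSelection(fragments=(("A", 1, len(host_idx)),), label="host")
    guest = UnitSelection(fragments=(("B", 1, len(guest_idx)),), label="guest")
    return host, guest, structure
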