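"""3D Gaussian envelope and the theoretical hydrophobicity profile T.

The fuzzy-oil-drop model idealizes a water-soluble globule as a 3D
Gaussian "drop": hydrophobicity is highest at the centre and falls off
towards the polar surface.  The envelope is fitted to the unit's
effective atoms — centre at their mean, axes along the principal axes of
their covariance, and each sigma set so the most distant point along
that axis sits at 3 sigma.  Evaluating the (separable) Gaussian at every
effective atom and normalizing gives the theoretical profile T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure import EffectiveStructure

__all__ = ["GaussianEnvelope", "Profile", "fit_envelope", "t_profile"]

#: the "3-sigma" rule: the extreme coordinate along each principal axis
#: is placed at this many sigmas from the centre
DEFAULT_SIGMA_MULTIPLIER = 3.0
DEFAULT_SIGMA_FLOOR = 1.0  # Å


@dataclass(frozen=True)
class Profile:
    """A normalized per-residue hydrophobicity distribution.

    ``role`` tags the distribution: ``T`` (theoretical), ``O``
    (observed), ``R`` (uniform reference) or ``M`` (environment-
    modified).  Values are non-negative and sum to 1.
    """

    values: np.ndarray
    role: str
    unit_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.role not in ("T", "O", "R", "M"):
            raise ValueError(f"unknown profile role {self.role!r}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("profile needs a 1-D array of length >= 2")
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")
        total = float(self.values.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"profile not normalized (sum={total!r})")
        if self.role == "T" and np.any(self.values <= 0):
            raise ValueError("T profile values must be strictly positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def max_value(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class GaussianEnvelope:
    """Fitted 3D Gaussian: centre, per-axis sigmas, principal-axis frame.

    ``rotation`` has the principal axes as rows, so
    ``rotation @ (x - center)`` maps molecule coordinates into the
    envelope frame.
    """

    center: np.ndarray  # (3,) Å
    sigmas: np.ndarray  # (3,) Å, all > 0
    rotation: np.ndarray  # (3, 3) orthonormal, det +1

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "sigmas", np.asarray(self.sigmas, dtype=float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        if np.any(self.sigmas <= 0):
            raise ValueError(f"sigmas must be positive, got {self.sigmas}")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1")

    def to_frame(self, coords: np.ndarray) -> np.ndarray:
        """Map (N, 3) molecule coordinates into the envelope frame."""
        return (np.asarray(coords, dtype=float) - self.center) @ self.rotation.T


def fit_envelope(
    structure: EffectiveStructure,
    sigma_multiplier: float = DEFAULT_SIGMA_MULTIPLIER,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> GaussianEnvelope:
    """Span the 3D Gaussian over a structural unit.

    centre = mean effective position; axes = principal axes of the
    effective-position covariance; per-axis
    ``sigma = max |coordinate along axis| / sigma_multiplier``, floored
    at ``sigma_floor`` (degenerate geometry triggers a warning).
    """
    coords = structure.coords
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered / len(centered)
    eigvals, eigvecs = np.linalg.eigh(cov)
    # descending variance order; rows of `rotation` are the axes
    order = np.argsort(eigvals)[::-1]
    axes = eigvecs[:, order].T
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    local = centered @ axes.T
    extents = np.abs(local).max(axis=0)
    sigmas = extents / sigma_multiplier
    if np.any(sigmas < sigma_floor):
        warnings.warn(
            f"degenerate envelope geometry: sigma(s) {sigmas} floored at {sigma_floor} Å",
            stacklevel=2,
        )
        sigmas = np.maximum(sigmas, sigma_floor)
    return GaussianEnvelope(center=center, sigmas=sigmas, rotation=axes)


def t_profile(envelope: GaussianEnvelope, structure: EffectiveStructure) -> Profile:
    """Theoretical profile: the separable Gaussian at each effective atom.

    ``T_i`` is the product of the three axis-wise Gaussian factors at
    residue *i*'s position in the envelope frame, normalized over the
    unit.  All values are strictly positive.
    """
    local = envelope.to_frame(structure.coords)
    log_t = -0.5 * np.sum((local / envelope.sigmas) ** 2, axis=1)
    # subtract the max before exponentiating for numerical safety
    t = np.exp(log_t - log_t.max())
    return Profile(values=t / t.sum(), role="T", unit_label=structure.unit_label)
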