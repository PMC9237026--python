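"""Quasi-sign-stability (QSS).

QSS asks how often a community (Jacobian) matrix whose *sign pattern* is
fixed by the food-web topology is locally stable when the interaction
magnitudes are drawn at random.  For a link "j eats i": the prey benefits
the predator (J[pred, prey] > 0) and the predator harms the prey
(J[prey, pred] < 0).  Every node is self-limited (negative diagonal) —
without universal self-limitation virtually no large random web is ever
stable and the index carries no contrast.  The QSS index is the proportion
of sampled Jacobians whose eigenvalues all have negative real part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .foodweb import FoodWeb, to_diet_matrix

__all__ = [
    "CommunityMatrixSpec",
    "QSSResult",
    "sample_jacobian",
    "is_locally_stable",
    "qss",
]


@dataclass
class CommunityMatrixSpec:
    """How to turn topology into random Jacobians.

    max_magnitude
        Off-diagonal magnitudes ~ Uniform(0, max_magnitude).
    diagonal_low
        Diagonals ~ Uniform(diagonal_low, 0); more negative means stronger
        self-limitation.
    weighted
        Scale both the positive (prey->predator) and negative
        (predator->prey) magnitudes of a link by its diet proportion.
    self_limit_all
        Self-limit every node; if false, only basal nodes.
    """

    max_magnitude: float = 1.0
    diagonal_low: float = -1.0
    weighted: bool = False
    self_limit_all: bool = True

    def __post_init__(self) -> None:
        if self.max_magnitude <= 0:
            raise ValueError("max_magnitude must be positive")
        if self.diagonal_low >= 0:
            raise ValueError("diagonal_low must be negative")


@dataclass
class QSSResult:
    proportion_stable: float
    n_samples: int
    n_stable: int
    seed: int
    weighted: bool
    se: float = 0.0
    max_eigenvalue_sample: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_stable <= self.n_samples
        self.se = float(
            np.sqrt(
                self.proportion_stable * (1 - self.proportion_stable) / self.n_samples
            )
        )


def _sign_structure(web: FoodWeb):
    """Index arrays for the predator/prey entries plus diet weights.

    Order matches ``web.node_ids``.  A cannibal self-link contributes only
    to its own (already negative) diagonal and is dropped from the
    off-diagonal pattern.
    """
    q = to_diet_matrix(web)
    prey_idx, pred_idx = np.nonzero(q.values)
    off = prey_idx != pred_idx
    prey_idx, pred_idx = prey_idx[off], pred_idx[off]
    weights = q.values[prey_idx, pred_idx]
    basal_mask = q.values.sum(axis=0) <= 0.5
    return q.node_order, prey_idx, pred_idx, weights, basal_mask


def sample_jacobian(
    web: FoodWeb,
    spec: CommunityMatrixSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one random Jacobian consistent with the web's sign structure."""
    spec = spec or CommunityMatrixSpec()
    rng = rng or np.random.default_rng()
    order, prey_idx, pred_idx, weights, basal_mask = _sign_structure(web)
    return _draw(len(order), prey_idx, pred_idx, weights, basal_mask, spec, rng)


def _draw(n, prey_idx, pred_idx, weights, basal_mask, spec, rng) -> np.ndarray:
    j = np.zeros((n, n))
    k = len(prey_idx)
    pos = rng.uniform(0, spec.max_magnitude, size=k)
    neg = rng.uniform(0, spec.max_magnitude, size=k)
    if spec.weighted:
        pos = pos * weights
        neg = neg * weights
    # predator row gains from prey column; prey row loses to predator column
    j[pred_idx, prey_idx] += pos
    j[prey_idx, pred_idx] -= neg
    diag = rng.uniform(spec.diagonal_low, 0.0, size=n)
    if not spec.self_limit_all:
        diag = np.where(basal_mask, diag, 0.0)
    j[np.diag_indices(n)] = diag
    return j


def is_locally_stable(j: np.ndarray, tol: float = 1e-10) -> bool:
    """True iff every eigenvalue has real part < -tol."""
    j = np.asarray(j, dtype=float)
    if j.ndim != 2 or j.shape[0] != j.shape[1]:
        raise ValueError("Jacobian must be a square matrix")
    return bool(np.max(np.linalg.eigvals(j).real) < -tol)


def qss(
    web: FoodWeb,
    n: int = 10000,
    weighted: bool = False,
    seed: int = 0,
    spec: CommunityMatrixSpec | None = None,
    tol: float = 1e-10,
    keep_eigenvalues: int = 0,
) -> QSSResult:
    """Estimate QSS with ``n`` random Jacobians; deterministic given seed.

    ``keep_eigenvalues`` retains the leading-eigenvalue real part of that
    many draws (diagnostics / plotting).
    """
    if n < 1:
        raise ValueError("need at least one sample")
    if spec is None:
        spec = CommunityMatrixSpec(weighted=weighted)
    else:
        spec.weighted = weighted
    rng = np.random.default_rng(seed)
    order, prey_idx, pred_idx, weights, basal_mask = _sign_structure(web)
    dim = len(order)
    n_stable = 0
    kept: list[float] = []
    for i in range(n):
        j = _draw(dim, prey_idx, pred_idx, weights, basal_mask, spec, rng)
        max_re = float(np.max(np.linalg.eigvals(j).real))
        if max_re < -tol:
            n_stable += 1
        if i < keep_eigenvalues:
            kept.append(max_re)
    return QSSResult(
        proportion_stable=n_stable / n,
        n_samples=n,
        n_stable=n_stable,
        seed=seed,
        weighted=weighted,
        max_eigenvalue_sample=kept,
    )
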