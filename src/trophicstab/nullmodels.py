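"""Null models: curveball topology randomization and column-sum-preserving
weight shuffles, plus a harness building metric null distributions.

The curveball move picks two predators (columns of the prey x predator
support) and trades a random subset of the prey each holds exclusively.
Every trade preserves each predator's number of prey (column sums) and
each prey's number of predators (row sums), so the basal/consumer identity
of every node is invariant.  After a topology randomization, a predator's
original multiset of diet proportions is re-dealt uniformly at random over
its (new) prey set — degree preservation guarantees the multiset fits, and
column sums stay exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .foodweb import DietMatrix, FoodWeb, from_diet_matrix, to_diet_matrix
from .metrics import TrophicSolveError, mean_trophic_level, omnivory, trophic_levels
from .modularity import FAST_SCHEDULE, AnnealingSchedule, find_best_partition

__all__ = [
    "NullEnsemble",
    "curveball",
    "shuffle_weights",
    "randomize_web",
    "null_distribution",
]

#: Default curveball trades per randomization, times the node count.
TRADES_PER_NODE = 5

METRICS = ("mTL", "omnivory", "modularity")


@dataclass
class NullEnsemble:
    """A metric's values over randomized webs plus the recipe that made them."""

    metric: str
    values: np.ndarray
    recipe: dict = field(default_factory=dict)
    source: str = ""
    n_redraws: int = 0

    def median(self) -> float:
        return float(np.median(self.values))


def curveball(
    a: np.ndarray,
    n_trades: int,
    seed: int | np.random.Generator = 0,
    fix_diagonal: bool = False,
) -> np.ndarray:
    """Randomize a 0/1 matrix by ``n_trades`` curveball trades on column
    pairs; all row and column sums are preserved exactly.

    With ``fix_diagonal`` (square matrices whose rows and columns index the
    same nodes) diagonal entries are frozen: existing self-links stay and
    no trade may create one — the food-web null should neither erase real
    cannibalism nor invent it.
    """
    if n_trades < 0:
        raise ValueError("n_trades must be >= 0")
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError("curveball needs a binary matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = a.astype(np.int8).copy()
    n_cols = out.shape[1]
    if n_cols < 2:
        return out
    cols = [np.flatnonzero(out[:, j]) for j in range(n_cols)]
    for _ in range(n_trades):
        j1, j2 = rng.choice(n_cols, size=2, replace=False)
        s1, s2 = cols[j1], cols[j2]
        only1 = np.setdiff1d(s1, s2, assume_unique=True)
        only2 = np.setdiff1d(s2, s1, assume_unique=True)
        frozen1 = frozen2 = np.empty(0, dtype=only1.dtype)
        if fix_diagonal:
            # row j1 may never sit in column j1 (likewise j2): pin those
            # rows to the side they are on
            frozen1 = only1[(only1 == j1) | (only1 == j2)]
            frozen2 = only2[(only2 == j1) | (only2 == j2)]
            only1 = only1[(only1 != j1) & (only1 != j2)]
            only2 = only2[(only2 != j1) & (only2 != j2)]
        if len(only1) == 0 or len(only2) == 0:
            continue
        # reshuffle the union of exclusive prey and re-split it, keeping
        # each predator's count — the canonical (symmetric, aperiodic) trade
        shared = np.intersect1d(s1, s2, assume_unique=True)
        pool = np.concatenate([only1, only2])
        rng.shuffle(pool)
        cols[j1] = np.sort(np.concatenate([shared, frozen1, pool[: len(only1)]]))
        cols[j2] = np.sort(np.concatenate([shared, frozen2, pool[len(only1):]]))
    res = np.zeros_like(out)
    for j, rows in enumerate(cols):
        res[rows, j] = 1
    return res


def shuffle_weights(
    q: DietMatrix, seed: int | np.random.Generator = 0
) -> DietMatrix:
    """Permute each predator column's positive weights over its prey
    positions; column sums are exactly preserved."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = q.values.copy()
    for j in range(q.n):
        rows = np.flatnonzero(values[:, j])
        if rows.size > 1:
            values[rows, j] = values[rows[rng.permutation(rows.size)], j]
    return DietMatrix(values, list(q.node_order))


def _reassign_weights(
    support: np.ndarray, original: DietMatrix, rng: np.random.Generator
) -> np.ndarray:
    """Deal each predator's original weight multiset onto its new prey set."""
    values = np.zeros(support.shape, dtype=float)
    for j in range(support.shape[1]):
        rows = np.flatnonzero(support[:, j])
        if rows.size == 0:
            continue
        w = original.values[original.values[:, j] > 0, j]
        assert w.size == rows.size  # curveball preserves column sums
        values[rows[rng.permutation(rows.size)], j] = w
    return values


def randomize_web(
    web: FoodWeb,
    weighted: bool = False,
    trades_per_node: int = TRADES_PER_NODE,
    seed: int | np.random.Generator = 0,
) -> FoodWeb:
    """One degree-preserving randomization of ``web``.

    Topology first (curveball on the binary support), then — in weighted
    mode — the diet proportions re-dealt within each predator column.  In
    unweighted mode the randomized web gets equal shares per predator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = to_diet_matrix(web)
    support = curveball(q.binary(), trades_per_node * q.n, rng, fix_diagonal=True)
    if weighted:
        values = _reassign_weights(support, q, rng)
    else:
        counts = support.sum(axis=0)
        values = np.zeros(support.shape, dtype=float)
        nz = counts > 0
        values[:, nz] = support[:, nz].astype(float) / counts[nz]
    matrix = DietMatrix(values, list(q.node_order))
    return from_diet_matrix(matrix, nodes=web.nodes, name=f"{web.name}-null")


def _metric_value(
    metric: str,
    web: FoodWeb,
    weighted: bool,
    epsilon: float,
    schedule: AnnealingSchedule,
    seed: int,
) -> float:
    if metric == "mTL":
        return mean_trophic_level(trophic_levels(web, weighted=weighted))
    if metric == "omnivory":
        return omnivory(web, weighted=weighted, epsilon=epsilon)
    if metric == "modularity":
        return find_best_partition(web, weighted=weighted, schedule=schedule, seed=seed).q
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def null_distribution(
    web: FoodWeb,
    metric: str,
    n: int = 1000,
    weighted: bool = False,
    seed: int = 0,
    trades_per_node: int = TRADES_PER_NODE,
    epsilon: float = 1.0,
    schedule: AnnealingSchedule | None = None,
    max_redraw_frac: float = 0.25,
) -> NullEnsemble:
    """Distribution of ``metric`` over ``n`` degree-preserving
    randomizations of ``web``.

    Randomized topologies whose trophic-level system is singular (a new
    consumer loop with no basal leakage) are redrawn and counted; more than
    ``max_redraw_frac * n`` redraws (with a small absolute floor) aborts
    with advice.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    schedule = schedule or FAST_SCHEDULE
    rng = np.random.default_rng(seed)
    values = np.empty(n)
    n_redraws = 0
    for r in range(n):
        while True:
            null_web = randomize_web(
                web, weighted=weighted, trades_per_node=trades_per_node, seed=rng
            )
            try:
                values[r] = _metric_value(
                    metric, null_web, weighted, epsilon, schedule,
                    seed=int(rng.integers(2**31)),
                )
                break
            except TrophicSolveError:
                n_redraws += 1
                if n_redraws > max(5.0, max_redraw_frac * n):
                    raise RuntimeError(
                        "too many singular randomized webs; increase "
                        "trades_per_node or use unweighted mode"
                    )
    return NullEnsemble(
        metric=metric,
        values=values,
        recipe={
            "n": n,
            "seed": seed,
            "trades_per_node": trades_per_node,
            "weighted": weighted,
            "epsilon": epsilon,
        },
        source=web.name,
        n_redraws=n_redraws,
    )
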