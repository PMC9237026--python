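"""Trophic-level based network metrics.

The trophic level (TL) of a basal resource is 1; a consumer sits one level
above the (diet-weighted) mean of its prey:

    TL_j = 1 + sum_i q_ij * TL_i

with Q the prey-by-predator diet matrix.  Stacking over nodes this is the
linear system (I - Q^T) TL = 1, solved directly.  The
unweighted variant replaces each consumer's diet with equal shares over its
prey (the prey-averaged convention), so weighted and unweighted TLs differ
only through Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .foodweb import DietMatrix, FoodWeb, to_diet_matrix

__all__ = [
    "TrophicLevels",
    "MetricSet",
    "TrophicSolveError",
    "trophic_levels",
    "mean_trophic_level",
    "omnivory",
    "weighted_omnivory_index",
    "degree_table",
    "tl_class_fractions",
]

#: Max-norm residual allowed on the defining linear system.
SOLVE_RESIDUAL_TOL = 1e-9


class TrophicSolveError(ValueError):
    """The TL system is singular: some consumers form a loop with no diet
    leakage toward a basal resource."""


@dataclass
class TrophicLevels:
    """Per-node trophic levels plus which diet matrix produced them."""

    tl: dict[str, float]
    weighted: bool

    def as_array(self, order: list[str]) -> np.ndarray:
        return np.array([self.tl[i] for i in order])

    @property
    def max_tl(self) -> float:
        return max(self.tl.values())

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        """The k highest-TL nodes, ties broken by id."""
        return sorted(self.tl.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


@dataclass
class MetricSet:
    """One scenario's metric values (one weighting)."""

    mTL: float
    omnivory: float
    modularity: float | None = None
    qss: float | None = None
    weighted: bool = False
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "mTL": self.mTL,
            "omnivory": self.omnivory,
            "modularity": self.modularity,
            "qss": self.qss,
            "weighted": self.weighted,
        }
        out.update(self.extras)
        return out


def trophic_levels(q: DietMatrix | FoodWeb, weighted: bool = True) -> TrophicLevels:
    """Solve (I - Q^T) TL = 1 for the trophic levels.

    Parameters
    ----------
    q
        Diet matrix (or a web, converted internally).
    weighted
        If false, Q is first replaced by equal shares per consumer.

    Raises
    ------
    TrophicSolveError
        If the system is singular; the offending strongly connected
        component is named in the message.
    """
    if isinstance(q, FoodWeb):
        q = to_diet_matrix(q)
    if not weighted:
        q = q.equal_shares()
    n = q.n
    if n == 0:
        return TrophicLevels({}, weighted)
    a = np.eye(n) - q.values.T
    try:
        tl = np.linalg.solve(a, np.ones(n))
    except np.linalg.LinAlgError:
        tl = np.full(n, np.nan)
    if not np.all(np.isfinite(tl)) or (
        np.max(np.abs(a @ tl - 1.0)) > SOLVE_RESIDUAL_TOL
    ):
        raise TrophicSolveError(
            "trophic-level system is singular; offending component(s): "
            f"{_singular_components(q)}"
        )
    # exact 1 for basal nodes (zero diet column), clearing solver round-off
    basal = q.values.sum(axis=0) <= 0.5
    tl[basal] = 1.0
    return TrophicLevels(dict(zip(q.node_order, tl.tolist())), weighted)


def _singular_components(q: DietMatrix) -> list[list[str]]:
    """Strongly connected consumer groups whose diets never leak outside
    the group — these make (I - Q^T) singular."""
    n_comp, labels = sp.csgraph.connected_components(
        sp.csr_matrix((q.values.T > 0).astype(np.int8)), connection="strong"
    )
    out = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            continue
        # total diet mass kept inside the component, per member
        inside = q.values[np.ix_(members, members)].sum(axis=0)
        col_sums = q.values[:, members].sum(axis=0)
        if members.size > 1 or q.values[members[0], members[0]] > 0:
            if np.allclose(inside, col_sums) and col_sums.max() > 0:
                out.append([q.node_order[i] for i in members])
    return out


def mean_trophic_level(
    tls: TrophicLevels, include: set[str] | None = None
) -> float:
    """Arithmetic mean TL over ``include`` (default: all nodes)."""
    ids = set(tls.tl) if include is None else set(include)
    if not ids:
        raise ValueError("empty node filter for mean trophic level")
    return float(np.mean([tls.tl[i] for i in ids]))


def omnivory(
    q: DietMatrix | FoodWeb,
    tls: TrophicLevels | None = None,
    weighted: bool = False,
    epsilon: float = 1.0,
) -> float:
    """Network-level omnivory.

    Unweighted: the fraction of all nodes that are consumers whose prey
    trophic levels span more than ``epsilon`` (max prey TL - min prey TL >
    epsilon).  With fractional TLs, ``epsilon`` controls how different two
    resources must be to count as "more than one trophic level"; the
    default 1.0 requires a full level.

    Weighted: the classical omnivory index — for each consumer the
    diet-weighted variance of its prey TLs, averaged over consumers.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if isinstance(q, FoodWeb):
        q = to_diet_matrix(q)
    if tls is None:
        tls = trophic_levels(q, weighted=weighted)
    values = q.values if weighted else q.equal_shares().values
    tl = tls.as_array(q.node_order)
    consumer_cols = np.flatnonzero(values.sum(axis=0) > 0.5)
    if consumer_cols.size == 0:
        return 0.0

    if not weighted:
        n_omni = 0
        for j in consumer_cols:
            prey_tl = tl[values[:, j] > 0]
            if prey_tl.max() - prey_tl.min() > epsilon:
                n_omni += 1
        return n_omni / q.n

    total = 0.0
    for j in consumer_cols:
        w = values[:, j]
        mean_prey = float(w @ tl)
        total += float(w @ (tl - mean_prey) ** 2)
    return total / consumer_cols.size


def weighted_omnivory_fraction(
    q: DietMatrix | FoodWeb,
    tls: TrophicLevels | None = None,
    epsilon: float = 1.0,
) -> float:
    """Thresholded companion to the weighted index: fraction of nodes whose
    weighted prey-TL standard deviation exceeds ``epsilon``/2."""
    if isinstance(q, FoodWeb):
        q = to_diet_matrix(q)
    if tls is None:
        tls = trophic_levels(q, weighted=True)
    tl = tls.as_array(q.node_order)
    consumer_cols = np.flatnonzero(q.values.sum(axis=0) > 0.5)
    n_omni = 0
    for j in consumer_cols:
        w = q.values[:, j]
        mean_prey = float(w @ tl)
        var = float(w @ (tl - mean_prey) ** 2)
        if np.sqrt(var) > epsilon / 2:
            n_omni += 1
    return n_omni / q.n if q.n else 0.0


# alias used by reports
weighted_omnivory_index = omnivory


def degree_table(web: FoodWeb) -> dict[str, int]:
    """Total degree (in + out, self-links counted once) per node, ordered by
    degree descending then id."""
    deg = {nid: 0 for nid in web.node_ids}
    for link in web.links:
        deg[link.predator] += 1
        if not link.is_self_link:
            deg[link.prey] += 1
    return dict(sorted(deg.items(), key=lambda kv: (-kv[1], kv[0])))


def tl_class_fractions(web: FoodWeb) -> tuple[float, float, float]:
    """(top %, intermediate %, basal %) of all nodes.

    basal = no prey; top = has prey but no predators; intermediate = both.
    Returned as percentages (not rounded); reports round to integers.
    """
    basal = set(web.basal_nodes())
    top = set(web.top_nodes())
    n = web.n_nodes
    if n == 0:
        return (0.0, 0.0, 0.0)
    n_basal = len(basal)
    n_top = len(top)
    n_mid = n - n_basal - n_top
    return (100.0 * n_top / n, 100.0 * n_mid / n, 100.0 * n_basal / n)
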