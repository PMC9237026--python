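"""Food-web data model and on-disk representations.

A food web is a directed network of consumer-resource links.  Links point
from the predator to its prey and carry the prey's proportion in the
predator's diet, so every consumer's outgoing weights sum to one.  The
matrix view (:class:`DietMatrix`) is oriented prey-rows x predator-columns:
column *j* is predator *j*'s diet composition, and null models that
"randomize weights keeping the column sum fixed" are literal column
operations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Node",
    "Link",
    "FoodWeb",
    "DietMatrix",
    "FoodWebError",
    "read_edge_list",
    "write_edge_list",
    "write_graphml",
    "to_diet_matrix",
    "from_diet_matrix",
]

#: Recognized node kinds. ``fishery`` and ``discard`` are the scenario
#: nodes and may occur at most once per web.
NODE_KINDS = ("species", "trophospecies", "detritus", "fishery", "discard")

#: Tolerance on a consumer's diet sum after normalization.
DIET_SUM_TOL = 1e-6
#: How far a raw diet sum may deviate from 1 and still be renormalized.
RENORM_TOL = 1e-3


class FoodWebError(ValueError):
    """Raised when a web violates a structural invariant."""


@dataclass(frozen=True)
class Node:
    """A species, trophospecies or scenario node."""

    id: str
    label: str = ""
    kind: str = "species"

    def __post_init__(self) -> None:
        if not self.id:
            raise FoodWebError("node id must be non-empty")
        if self.kind not in NODE_KINDS:
            raise FoodWebError(f"unknown node kind {self.kind!r}")
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass(frozen=True)
class Link:
    """A directed predator -> prey link weighted by diet proportion."""

    predator: str
    prey: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (self.weight > 0):
            raise FoodWebError(
                f"link {self.predator}->{self.prey} has non-positive weight"
            )

    @property
    def is_self_link(self) -> bool:
        return self.predator == self.prey


class FoodWeb:
    """Validated food web: unique nodes, weighted links, diet sums = 1.

    Parameters
    ----------
    nodes
        Iterable of :class:`Node`; ids must be unique.
    links
        Iterable of :class:`Link`; duplicate (predator, prey) pairs are
        rejected, endpoints must exist.
    name
        Scenario label (e.g. ``"non-fishing"``).
    renormalize
        If true, consumer diet sums deviating from 1 by at most
        ``RENORM_TOL`` are rescaled to sum exactly to 1; larger deviations
        are always an error.
    require_basal
        Every real food web needs at least one basal resource; relax only
        for abstract graphs (e.g. modularity toy cases).
    """

    def __init__(
        self,
        nodes: Iterable[Node],
        links: Iterable[Link],
        name: str = "web",
        renormalize: bool = True,
        require_basal: bool = True,
    ) -> None:
        self.name = name
        self._nodes: dict[str, Node] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise FoodWebError(f"duplicate node id {node.id!r}")
            self._nodes[node.id] = node
        for kind in ("fishery", "discard"):
            n_kind = sum(1 for n in self._nodes.values() if n.kind == kind)
            if n_kind > 1:
                raise FoodWebError(f"at most one {kind} node allowed, found {n_kind}")

        self._links: dict[tuple[str, str], Link] = {}
        for link in links:
            key = (link.predator, link.prey)
            if key in self._links:
                raise FoodWebError(f"duplicate link {key}")
            for endpoint in key:
                if endpoint not in self._nodes:
                    raise FoodWebError(f"link endpoint {endpoint!r} not in nodes")
            self._links[key] = link

        if renormalize:
            self._renormalize_diets()
        self._validate(require_basal)

    # -- construction helpers -------------------------------------------------

    def _renormalize_diets(self) -> None:
        sums: dict[str, float] = {}
        for link in self._links.values():
            sums[link.predator] = sums.get(link.predator, 0.0) + link.weight
        for predator, total in sums.items():
            if abs(total - 1.0) <= DIET_SUM_TOL:
                continue
            if abs(total - 1.0) > RENORM_TOL:
                raise FoodWebError(
                    f"diet of {predator!r} sums to {total:.6f}, deviation exceeds "
                    f"renormalization tolerance {RENORM_TOL}"
                )
            for key, link in list(self._links.items()):
                if link.predator == predator:
                    self._links[key] = Link(link.predator, link.prey, link.weight / total)

    def _validate(self, require_basal: bool = True) -> None:
        sums: dict[str, float] = {}
        for link in self._links.values():
            sums[link.predator] = sums.get(link.predator, 0.0) + link.weight
        for predator, total in sums.items():
            if abs(total - 1.0) > DIET_SUM_TOL:
                raise FoodWebError(
                    f"diet of {predator!r} sums to {total:.8f} (tolerance {DIET_SUM_TOL})"
                )
        if require_basal and self._nodes and not self.basal_nodes():
            raise FoodWebError("web has no basal node (every node has prey)")

    # -- accessors -------------------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        """Node ids in sorted (deterministic) order."""
        return sorted(self._nodes)

    @property
    def nodes(self) -> list[Node]:
        return [self._nodes[i] for i in self.node_ids]

    @property
    def links(self) -> list[Link]:
        return [self._links[k] for k in sorted(self._links)]

    def node(self, node_id: str) -> Node:
        return self._nodes[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_links(self) -> int:
        return len(self._links)

    def prey_of(self, predator: str) -> dict[str, float]:
        """Map prey id -> diet proportion for one predator."""
        return {
            l.prey: l.weight for l in self._links.values() if l.predator == predator
        }

    def predators_of(self, prey: str) -> list[str]:
        return sorted(l.predator for l in self._links.values() if l.prey == prey)

    def basal_nodes(self) -> list[str]:
        """Nodes with no prey; self-links are ignored for basal status."""
        consumers = {l.predator for l in self._links.values() if not l.is_self_link}
        return sorted(set(self._nodes) - consumers)

    def consumer_nodes(self) -> list[str]:
        consumers = {l.predator for l in self._links.values() if not l.is_self_link}
        return sorted(consumers)

    def top_nodes(self) -> list[str]:
        """Consumers with no predators (self-links ignored)."""
        preyed = {l.prey for l in self._links.values() if not l.is_self_link}
        return sorted(set(self.consumer_nodes()) - preyed)

    def self_links(self) -> list[Link]:
        """Cannibalistic links, flagged but legal."""
        return [l for l in self.links if l.is_self_link]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodWeb):
            return NotImplemented
        if set(self._nodes) != set(other._nodes):
            return False
        if any(self._nodes[i] != other._nodes[i] for i in self._nodes):
            return False
        if set(self._links) != set(other._links):
            return False
        return all(
            abs(self._links[k].weight - other._links[k].weight) < 1e-9
            for k in self._links
        )

    def __repr__(self) -> str:
        return f"FoodWeb({self.name!r}, nodes={self.n_nodes}, links={self.n_links})"


@dataclass
class DietMatrix:
    """Prey-by-predator matrix Q; ``values[i, j]`` is the share of prey *i*
    in predator *j*'s diet.  Consumer columns sum to 1, basal columns are
    zero.  Binarizing the entries recovers the unweighted adjacency."""

    values: np.ndarray
    node_order: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_order)
        if self.values.shape != (n, n):
            raise FoodWebError("DietMatrix must be square over node_order")
        if (self.values < 0).any() or (self.values > 1 + 1e-12).any():
            raise FoodWebError("diet proportions must lie in [0, 1]")
        sums = self.values.sum(axis=0)
        bad = np.flatnonzero((sums > DIET_SUM_TOL) & (np.abs(sums - 1.0) > DIET_SUM_TOL))
        if bad.size:
            raise FoodWebError(
                f"consumer columns {[self.node_order[i] for i in bad]} do not sum to 1"
            )

    @property
    def n(self) -> int:
        return len(self.node_order)

    def index(self, node_id: str) -> int:
        return self.node_order.index(node_id)

    def binary(self) -> np.ndarray:
        """0/1 adjacency support (prey x predator)."""
        return (self.values > 0).astype(np.int8)

    def consumer_columns(self) -> np.ndarray:
        """Boolean mask of columns with at least one prey."""
        return self.values.sum(axis=0) > 0.5

    def equal_shares(self) -> "DietMatrix":
        """Unweighted view: each consumer's diet replaced by equal shares."""
        b = self.binary().astype(float)
        counts = b.sum(axis=0)
        out = np.zeros_like(b)
        nz = counts > 0
        out[:, nz] = b[:, nz] / counts[nz]
        return DietMatrix(out, list(self.node_order))


def to_diet_matrix(web: FoodWeb) -> DietMatrix:
    """Build the prey-by-predator diet matrix with sorted node order."""
    order = web.node_ids
    idx = {nid: i for i, nid in enumerate(order)}
    q = np.zeros((len(order), len(order)))
    for link in web.links:
        q[idx[link.prey], idx[link.predator]] = link.weight
    return DietMatrix(q, order)


def from_diet_matrix(
    matrix: DietMatrix,
    nodes: Sequence[Node] | None = None,
    name: str = "web",
) -> FoodWeb:
    """Inverse of :func:`to_diet_matrix` (round trip is the identity on links)."""
    if nodes is None:
        nodes = [Node(nid) for nid in matrix.node_order]
    links = []
    prey_idx, pred_idx = np.nonzero(matrix.values)
    for i, j in zip(prey_idx.tolist(), pred_idx.tolist()):
        links.append(
            Link(matrix.node_order[j], matrix.node_order[i], float(matrix.values[i, j]))
        )
    return FoodWeb(nodes, links, name=name)


# -- on-disk formats ----------------------------------------------------------


def _read_node_table(path: str | Path, column_map: Mapping[str, str]) -> dict[str, Node]:
    nodes: dict[str, Node] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            nid = row[column_map.get("id", "id")].strip()
            label = row.get(column_map.get("label", "label"), nid) or nid
            kind = (row.get(column_map.get("kind", "kind"), "species") or "species").lower()
            nodes[nid] = Node(nid, label.strip(), kind.strip())
    return nodes


def read_edge_list(
    path: str | Path,
    node_table: str | Path | None = None,
    name: str | None = None,
    column_map: Mapping[str, str] | None = None,
    renormalize: bool = True,
) -> FoodWeb:
    """Read a web from a delimited edge list.

    The file must have header columns ``predator``, ``prey`` and optionally
    ``weight``; names can be remapped via ``column_map`` (the deposited
    data's column names vary between archives).  Without a weight column
    the web is unweighted and each predator's prey get equal shares.  Node
    kinds come from ``node_table`` (CSV ``id,label,kind``) when given.
    """
    column_map = dict(column_map or {})
    pred_col = column_map.get("predator", "predator")
    prey_col = column_map.get("prey", "prey")
    weight_col = column_map.get("weight", "weight")

    rows: list[tuple[str, str, float | None]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FoodWebError(f"{path}: empty file")
        has_weight = weight_col in reader.fieldnames
        for row in reader:
            w = float(row[weight_col]) if has_weight else None
            rows.append((row[pred_col].strip(), row[prey_col].strip(), w))
    if not rows:
        raise FoodWebError(f"{path}: no links")

    known = _read_node_table(node_table, column_map) if node_table else {}
    ids = {r[0] for r in rows} | {r[1] for r in rows} | set(known)
    nodes = [known.get(nid, Node(nid)) for nid in sorted(ids)]

    if all(r[2] is None for r in rows):
        counts: dict[str, int] = {}
        for pred, _, _ in rows:
            counts[pred] = counts.get(pred, 0) + 1
        links = [Link(p, q, 1.0 / counts[p]) for p, q, _ in rows]
    else:
        links = [Link(p, q, w if w is not None else 1.0) for p, q, w in rows]

    return FoodWeb(nodes, links, name=name or Path(path).stem, renormalize=renormalize)


def write_edge_list(
    web: FoodWeb, path: str | Path, node_table: str | Path | None = None
) -> None:
    """Write ``predator,prey,weight`` CSV (weights at 12 significant digits
    so diet sums survive a round trip); optionally a node table alongside."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["predator", "prey", "weight"])
        for link in web.links:
            writer.writerow([link.predator, link.prey, f"{link.weight:.12g}"])
    if node_table is not None:
        with open(node_table, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "label", "kind"])
            for node in web.nodes:
                writer.writerow([node.id, node.label, node.kind])


def write_graphml(web: FoodWeb, path: str | Path) -> None:
    """Export to GraphML with ``weight`` and ``kind`` attributes."""
    g = nx.DiGraph(name=web.name)
    for node in web.nodes:
        g.add_node(node.id, label=node.label, kind=node.kind)
    for link in web.links:
        g.add_edge(link.predator, link.prey, weight=link.weight)
    nx.write_graphml(g, path)


def to_networkx(web: FoodWeb) -> nx.DiGraph:
    """DiGraph view (predator -> prey edges, diet-proportion weights)."""
    g = nx.DiGraph(name=web.name)
    for node in web.nodes:
        g.add_node(node.id, label=node.label, kind=node.kind)
    for link in web.links:
        g.add_edge(link.predator, link.prey, weight=link.weight)
    return g
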