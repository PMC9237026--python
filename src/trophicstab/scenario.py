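"""Fishing-scenario construction.

The fishing web is the non-fishing web plus two nodes: a fishery that
consumes the caught species (a pseudo top predator — nothing preys on it)
and a discard node that acts as a novel basal resource for scavengers and
opportunists.  Each discard consumer devotes a share of its diet to the
discard; its natural diet weights are rescaled by (1 - share) so every
diet still sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .foodweb import FoodWeb, FoodWebError, Link, Node

__all__ = ["FisheryRules", "build_fishing_web", "strip_fishing_nodes"]

FISHERY_ID = "Fishery"
DISCARD_ID = "Discard"


@dataclass
class FisheryRules:
    """Which species the trawl catches and who scavenges the discards.

    capture_weights
        The fishery's diet composition over ``caught`` (must sum to 1);
        ``None`` means equal shares.
    discard_shares
        Per consumer, the proportion of its rebalanced diet taken from the
        discard node; a plain float applies to every discard consumer.
    """

    caught: list[str]
    discard_consumers: list[str] = field(default_factory=list)
    capture_weights: dict[str, float] | None = None
    discard_shares: dict[str, float] | float = 0.1

    def __post_init__(self) -> None:
        if not self.caught:
            raise FoodWebError("caught set must be non-empty")
        if self.capture_weights is not None:
            if set(self.capture_weights) != set(self.caught):
                raise FoodWebError("capture_weights keys must equal the caught set")
            total = sum(self.capture_weights.values())
            if abs(total - 1.0) > 1e-6:
                raise FoodWebError(f"capture weights sum to {total}, not 1")

    def share_for(self, consumer: str) -> float:
        if isinstance(self.discard_shares, dict):
            share = self.discard_shares[consumer]
        else:
            share = self.discard_shares
        if not (0 < share < 1):
            raise FoodWebError(f"discard share {share} for {consumer!r} not in (0,1)")
        return float(share)


def build_fishing_web(base: FoodWeb, rules: FisheryRules) -> FoodWeb:
    """Add the fishery and discard nodes to ``base``.

    The link count grows by exactly ``len(caught) + len(discard_consumers)``;
    removing the two nodes and rescaling diets back recovers ``base``.
    """
    for nid in (FISHERY_ID, DISCARD_ID):
        if nid in base:
            raise FoodWebError(f"base web already contains a {nid!r} node")
    missing = [
        nid
        for nid in list(rules.caught) + list(rules.discard_consumers)
        if nid not in base
    ]
    if missing:
        raise FoodWebError(f"rule ids not in base web: {missing}")

    nodes = list(base.nodes) + [
        Node(FISHERY_ID, "Fishery", "fishery"),
        Node(DISCARD_ID, "Discard", "discard"),
    ]

    if rules.capture_weights is None:
        capture = {nid: 1.0 / len(rules.caught) for nid in rules.caught}
    else:
        capture = dict(rules.capture_weights)

    discard_consumers = set(rules.discard_consumers)
    links: list[Link] = []
    for link in base.links:
        if link.predator in discard_consumers:
            share = rules.share_for(link.predator)
            links.append(Link(link.predator, link.prey, link.weight * (1 - share)))
        else:
            links.append(link)
    for consumer in sorted(discard_consumers):
        links.append(Link(consumer, DISCARD_ID, rules.share_for(consumer)))
    for prey, w in sorted(capture.items()):
        links.append(Link(FISHERY_ID, prey, w))

    return FoodWeb(nodes, links, name=f"{base.name}-fishing")


def strip_fishing_nodes(web: FoodWeb, name: str | None = None) -> FoodWeb:
    """Inverse of :func:`build_fishing_web`: drop the fishery and discard
    nodes and rescale the former discard consumers' diets back to 1."""
    nodes = [n for n in web.nodes if n.kind not in ("fishery", "discard")]
    keep_ids = {n.id for n in nodes}
    scale: dict[str, float] = {}
    for link in web.links:
        if link.prey not in keep_ids and link.predator in keep_ids:
            scale[link.predator] = 1.0 - link.weight
    links = [
        Link(l.predator, l.prey, l.weight / scale.get(l.predator, 1.0))
        for l in web.links
        if l.predator in keep_ids and l.prey in keep_ids
    ]
    return FoodWeb(nodes, links, name=name or web.name.removesuffix("-fishing"))
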