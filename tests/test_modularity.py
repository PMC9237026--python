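import networkx as nx
import numpy as np
import pytest

from trophicstab import (
    AnnealingSchedule,
    FAST_SCHEDULE,
    FoodWeb,
    Link,
    Node,
    Partition,
    find_best_partition,
    modularity_value,
)
from trophicstab.foodweb import to_networkx
from trophicstab.synthetic import NicheParams, niche_model


def all_partitions(items):
    """Every set partition of ``items`` (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in all_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1:]
        yield [[first]] + sub


def brute_force_optimum(web, weighted=False):
    best = -np.inf
    for blocks in all_partitions(web.node_ids):
        part = Partition(
            {nid: k for k, block in enumerate(blocks) for nid in block}
        )
        best = max(best, modularity_value(web, part, weighted))
    return best


class TestModularityValue:
    def test_single_community_is_zero(self, two_cycles):
        part = Partition.single_community(two_cycles.node_ids)
        assert modularity_value(two_cycles, part) == pytest.approx(0.0)

    def test_two_disjoint_cycles(self, two_cycles):
        part = Partition({n: 0 if n in "ABC" else 1 for n in "ABCDEF"})
        # direct 6x6 summation: inside = 6/6, null = 2 * (3*3)/36
        assert modularity_value(two_cycles, part) == pytest.approx(0.5)

    def test_singletons_equal_minus_null_term(self, two_cycles):
        part = Partition.singletons(two_cycles.node_ids)
        # no self-links: only the diagonal null terms survive
        expected = -sum(1 * 1 for _ in range(6)) / 36
        assert modularity_value(two_cycles, part) == pytest.approx(expected)

    def test_matches_networkx_directed_modularity(self, two_cycles, rng):
        g = to_networkx(two_cycles)
        for _ in range(10):
            labels = rng.integers(0, 3, size=6)
            part = Partition(dict(zip(two_cycles.node_ids, labels.tolist())))
            comms = [
                {n for n, c in part.assignment.items() if c == k}
                for k in range(part.n_communities)
            ]
            assert modularity_value(two_cycles, part) == pytest.approx(
                nx.community.modularity(g, comms)
            )

    def test_weighted_equal_weight_web_equals_unweighted(self, two_cycles):
        part = Partition({n: 0 if n in "ABC" else 1 for n in "ABCDEF"})
        assert modularity_value(two_cycles, part, weighted=True) == pytest.approx(
            modularity_value(two_cycles, part, weighted=False)
        )

    def test_no_links_rejected(self):
        web = FoodWeb([Node("A")], [])
        with pytest.raises(ValueError):
            modularity_value(web, Partition({"A": 0}))


def two_cluster_web():
    """Two dense 5-node feeding hierarchies joined by one bridge link."""
    nodes = [Node(f"a{i}") for i in range(5)] + [Node(f"b{i}") for i in range(5)]
    prey: dict[str, list[str]] = {n.id: [] for n in nodes}
    for grp in ("a", "b"):
        for i in range(5):
            for j in range(i + 1, 5):
                prey[f"{grp}{i}"].append(f"{grp}{j}")
    prey["a0"].append("b0")
    links = [
        Link(pred, pr, 1.0 / len(ps)) for pred, ps in prey.items() for pr in ps
    ]
    return FoodWeb(nodes, links)


class TestAnnealing:
    def test_recovers_two_clusters(self):
        web = two_cluster_web()
        res = find_best_partition(web, seed=5, schedule=FAST_SCHEDULE)
        comp = Partition({n.id: 0 if n.id.startswith("a") else 1 for n in web.nodes})
        assert res.q >= modularity_value(web, comp) - 1e-12
        groups = {}
        for nid, c in res.partition.assignment.items():
            groups.setdefault(c, set()).add(nid)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset(f"a{i}" for i in range(5)),
            frozenset(f"b{i}" for i in range(5)),
        }

    def test_chain_best_q_nonnegative(self, chain3):
        res = find_best_partition(chain3, seed=1, schedule=FAST_SCHEDULE)
        assert res.q >= 0.0

    def test_deterministic_given_seed(self, two_cycles):
        r1 = find_best_partition(two_cycles, seed=9, schedule=FAST_SCHEDULE)
        r2 = find_best_partition(two_cycles, seed=9, schedule=FAST_SCHEDULE)
        assert r1.q == r2.q
        assert r1.partition.assignment == r2.partition.assignment

    @pytest.mark.parametrize("seed", range(5))
    def test_never_below_trivial_partitions(self, seed, two_cycles):
        res = find_best_partition(two_cycles, seed=seed, schedule=FAST_SCHEDULE)
        single = modularity_value(
            two_cycles, Partition.single_community(two_cycles.node_ids)
        )
        comp = modularity_value(
            two_cycles, Partition({n: 0 if n in "ABC" else 1 for n in "ABCDEF"})
        )
        assert res.q >= max(single, comp) - 1e-12

    def test_matches_exhaustive_optimum_on_small_web(self):
        web = niche_model(NicheParams(s=6, c=0.2, seed=3))
        target = brute_force_optimum(web)
        hits = sum(
            find_best_partition(web, seed=s).q >= target - 1e-9
            for s in range(20)
        )
        assert hits >= 19

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            AnnealingSchedule(cooling=1.5)
        with pytest.raises(ValueError):
            AnnealingSchedule(t0=-1.0)


class TestPartition:
    def test_contiguous_relabeling(self):
        p = Partition({"A": 5, "B": 2, "C": 5})
        assert set(p.assignment.values()) == {0, 1}

    def test_canonical_first_appearance(self):
        p = Partition({"A": 1, "B": 0, "C": 1}).canonical(["A", "B", "C"])
        assert p.assignment == {"A": 0, "B": 1, "C": 0}
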