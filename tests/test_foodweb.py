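import csv

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trophicstab import (
    DietMatrix,
    FoodWeb,
    FoodWebError,
    Link,
    Node,
    from_diet_matrix,
    read_edge_list,
    to_diet_matrix,
    write_edge_list,
    write_graphml,
)


def _write_csv(path, rows, header=("predator", "prey", "weight")):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


class TestReadEdgeList:
    def test_weighted_three_rows(self, tmp_path):
        p = tmp_path / "web.csv"
        _write_csv(p, [("A", "B", 0.6), ("A", "C", 0.4), ("B", "C", 1.0)])
        web = read_edge_list(p)
        assert web.n_nodes == 3 and web.n_links == 3
        assert web.prey_of("A") == pytest.approx({"B": 0.6, "C": 0.4})
        assert web.prey_of("B") == pytest.approx({"C": 1.0})

    def test_missing_weight_column_gives_equal_shares(self, tmp_path):
        p = tmp_path / "web.csv"
        _write_csv(p, [("A", "B"), ("A", "C"), ("B", "C")], header=("predator", "prey"))
        web = read_edge_list(p)
        assert web.prey_of("A") == pytest.approx({"B": 0.5, "C": 0.5})

    def test_node_table_sets_kinds(self, tmp_path):
        p = tmp_path / "web.csv"
        _write_csv(p, [("A", "B", 1.0)])
        n = tmp_path / "nodes.csv"
        _write_csv(n, [("A", "hake", "species"), ("B", "detritus", "detritus")],
                   header=("id", "label", "kind"))
        web = read_edge_list(p, node_table=n)
        assert web.node("B").kind == "detritus"
        assert web.node("A").label == "hake"

    def test_column_map(self, tmp_path):
        p = tmp_path / "web.csv"
        _write_csv(p, [("B", "A", 1.0)], header=("resource", "consumer", "w"))
        web = read_edge_list(
            p, column_map={"predator": "consumer", "prey": "resource", "weight": "w"}
        )
        assert web.prey_of("A") == pytest.approx({"B": 1.0})

    def test_small_deviation_renormalized(self, tmp_path):
        p = tmp_path / "web.csv"
        _write_csv(p, [("A", "B", 0.6004), ("A", "C", 0.4)])
        web = read_edge_list(p)
        assert sum(web.prey_of("A").values()) == pytest.approx(1.0, abs=1e-9)

    def test_large_deviation_rejected(self, tmp_path):
        p = tmp_path / "web.csv"
        _write_csv(p, [("A", "B", 0.6), ("A", "C", 0.3)])
        with pytest.raises(FoodWebError, match="diet"):
            read_edge_list(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "web.csv"
        p.write_text("predator,prey,weight\n")
        with pytest.raises(FoodWebError, match="no links"):
            read_edge_list(p)


class TestInvariants:
    def test_duplicate_link_rejected(self):
        with pytest.raises(FoodWebError, match="duplicate link"):
            FoodWeb([Node("A"), Node("B")], [Link("A", "B", 0.5), Link("A", "B", 0.5)])

    def test_duplicate_node_rejected(self):
        with pytest.raises(FoodWebError, match="duplicate node"):
            FoodWeb([Node("A"), Node("A")], [])

    def test_missing_endpoint_rejected(self):
        with pytest.raises(FoodWebError, match="endpoint"):
            FoodWeb([Node("A")], [Link("A", "B")])

    def test_two_fishery_nodes_rejected(self):
        with pytest.raises(FoodWebError, match="fishery"):
            FoodWeb([Node("F1", kind="fishery"), Node("F2", kind="fishery")], [])

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(FoodWebError):
            Link("A", "B", 0.0)

    def test_all_consumers_no_basal_rejected(self):
        with pytest.raises(FoodWebError, match="basal"):
            FoodWeb([Node("A"), Node("B")], [Link("A", "B"), Link("B", "A")])

    def test_self_links_flagged_and_ignored_for_basal(self):
        web = FoodWeb(
            [Node("A"), Node("B")],
            [Link("A", "B", 0.7), Link("A", "A", 0.3), Link("B", "B", 1.0)],
        )
        assert [l.prey for l in web.self_links()] == ["A", "B"]
        assert web.basal_nodes() == ["B"]


class TestDietMatrix:
    def test_orientation_prey_rows_predator_columns(self, diamond):
        q = to_diet_matrix(diamond)
        assert q.node_order == ["A", "B", "C"]
        np.testing.assert_allclose(q.values[:, 0], [0.0, 0.5, 0.5])  # A's diet
        np.testing.assert_allclose(q.values[:, 2], 0.0)  # basal C

    def test_basal_only_web_all_zero(self):
        web = FoodWeb([Node("A"), Node("B")], [])
        assert not to_diet_matrix(web).values.any()

    def test_round_trip_identity_on_links(self, diamond):
        back = from_diet_matrix(to_diet_matrix(diamond), nodes=diamond.nodes)
        assert back == diamond

    def test_binarize_recovers_topology(self, diamond):
        q = to_diet_matrix(diamond)
        assert q.binary().sum() == diamond.n_links

    def test_bad_column_sum_rejected(self):
        with pytest.raises(FoodWebError):
            DietMatrix(np.array([[0.0, 0.4], [0.0, 0.0]]), ["A", "B"])

    def test_consumer_columns_sum_to_one_after_load(self, scenario_pair):
        for web in scenario_pair:
            q = to_diet_matrix(web)
            sums = q.values.sum(axis=0)
            consumers = sums > 0.5
            np.testing.assert_allclose(sums[consumers], 1.0, atol=1e-6)


class TestWriteRead:
    def test_round_trip_exact(self, tmp_path, diamond):
        p, n = tmp_path / "w.csv", tmp_path / "n.csv"
        write_edge_list(diamond, p, node_table=n)
        assert read_edge_list(p, node_table=n) == diamond

    def test_weights_survive_round_trip_to_high_precision(self, tmp_path):
        w1 = 1.0 / 3.0
        web = FoodWeb(
            [Node(i) for i in "ABCD"],
            [Link("A", "B", w1), Link("A", "C", w1), Link("A", "D", 1 - 2 * w1)],
        )
        p = tmp_path / "w.csv"
        write_edge_list(web, p)
        back = read_edge_list(p)
        assert back.prey_of("A")["B"] == pytest.approx(w1, abs=1e-10)

    def test_empty_link_web_writes_header_only(self, tmp_path):
        web = FoodWeb([Node("A")], [])
        p = tmp_path / "w.csv"
        write_edge_list(web, p)
        assert p.read_text().strip() == "predator,prey,weight"

    def test_graphml_export_keeps_weights_and_kinds(self, tmp_path, diamond):
        p = tmp_path / "w.graphml"
        write_graphml(diamond, p)
        g = nx.read_graphml(p)
        assert g.edges["A", "B"]["weight"] == pytest.approx(0.5)
        assert g.nodes["C"]["kind"] == "species"


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_generated_webs_round_trip_through_csv(tmp_path_factory, seed):
    """write -> read is the identity on arbitrary generated webs."""
    from trophicstab import NicheParams, niche_model

    web = niche_model(NicheParams(s=12, c=0.15, seed=seed))
    tmp = tmp_path_factory.mktemp("roundtrip")
    write_edge_list(web, tmp / "w.csv", node_table=tmp / "n.csv")
    assert read_edge_list(tmp / "w.csv", node_table=tmp / "n.csv", name=web.name) == web
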