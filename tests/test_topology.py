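"""Centrality measures against closed forms and independent oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from netpharm import (
    Network,
    betweenness_centrality,
    closeness_centrality,
    column_medians,
    compute_all,
    degree_centrality,
    edge_clustering_coefficient,
    eigenvector_centrality,
    local_avg_connectivity,
    network_centrality,
)
from netpharm.topology import CentralityTable, MEASURES

import _oracles as oracle
from conftest import net_from_nx


class TestSmallGraphValues:
    def test_degree(self, k4, star5):
        assert set(degree_centrality(k4).values()) == {3}
        dc = degree_centrality(star5)
        assert dc["H"] == 5 and all(dc[f"L{i}"] == 1 for i in range(1, 6))
        net = Network.from_edges([("A", "B")], nodes=["Z"])
        assert degree_centrality(net)["Z"] == 0

    def test_betweenness_path(self, path3):
        bc = betweenness_centrality(path3)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_betweenness_k4_all_zero(self, k4):
        assert set(betweenness_centrality(k4).values()) == {0.0}

    def test_betweenness_star_hub_counts_leaf_pairs(self):
        net = Network.from_edges([("H", f"L{i}") for i in range(4)])
        assert betweenness_centrality(net)["H"] == math.comb(4, 2)

    def test_betweenness_ordered_pairs_doubles(self, path3):
        bc1 = betweenness_centrality(path3)
        bc2 = betweenness_centrality(path3, ordered_pairs=True)
        assert all(bc2[v] == 2 * bc1[v] for v in bc1)

    def test_closeness(self, k4, path3):
        assert set(closeness_centrality(k4).values()) == {1.0}
        cc = closeness_centrality(path3)
        assert cc["B"] == 1.0 and cc["A"] == pytest.approx(2 / 3)
        net = Network.from_edges([("A", "B")], nodes=["Z"])
        assert closeness_centrality(net)["Z"] == 0.0

    def test_eigenvector_closed_forms(self, k4):
        assert list(eigenvector_centrality(k4).values()) == pytest.approx([1.0] * 4)
        star = Network.from_edges([("H", f"L{i}") for i in range(4)])
        ec = eigenvector_centrality(star)
        assert ec["H"] == pytest.approx(1.0)
        assert ec["L0"] == pytest.approx(0.5, abs=1e-8)  # leaf/hub ratio 1/sqrt(4)... = 1/2
        edge = Network.from_edges([("A", "B")])
        assert eigenvector_centrality(edge) == {"A": pytest.approx(1.0), "B": pytest.approx(1.0)}

    def test_eigenvector_l2_norm_option(self, k4):
        ec = eigenvector_centrality(k4, norm="l2")
        assert np.isclose(sum(v * v for v in ec.values()), 1.0)

    def test_eigenvector_rejects_edgeless(self):
        with pytest.raises(ValueError):
            eigenvector_centrality(Network.from_edges([], nodes=["A", "B"]))

    def test_ecc(self, k4):
        assert edge_clustering_coefficient(k4, "A", "B") == 1.0  # z=2, min=2
        tri = Network.from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        assert edge_clustering_coefficient(tri, "A", "B") == 1.0  # z=1, min=1
        pend = Network.from_edges([("A", "B"), ("B", "C")])
        assert edge_clustering_coefficient(pend, "A", "B") == 0.0  # degree-1 endpoint
        with pytest.raises(ValueError):
            edge_clustering_coefficient(k4, "A", "Z")

    def test_network_centrality(self, k4, star5, path3):
        assert set(network_centrality(k4).values()) == {3.0}
        assert network_centrality(star5)["H"] == 0.0
        tri = Network.from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        assert network_centrality(tri)["A"] == 2.0
        assert network_centrality(path3)["B"] == 0.0

    def test_lac(self, k4, star5, path3):
        assert set(local_avg_connectivity(k4).values()) == {2.0}
        assert local_avg_connectivity(star5)["H"] == 0.0
        assert local_avg_connectivity(path3)["B"] == 0.0


class TestComputeAll:
    def test_k4_row(self, k4):
        table = compute_all(k4)
        for _, row in table.frame.iterrows():
            assert tuple(row) == pytest.approx((3, 0, 1, 1, 3, 2))

    def test_star_hub_row(self):
        net = Network.from_edges([("H", f"L{i}") for i in range(4)])
        row = compute_all(net).frame.loc["H"]
        assert tuple(row) == pytest.approx((4, 6, 1, 1, 0, 0))

    def test_columns_match_standalone_ops(self):
        net = net_from_nx(oracle.connected_er(40, 0.12, seed=5))
        table = compute_all(net).frame
        assert dict(table["DC"]) == degree_centrality(net)
        assert dict(table["BC"]) == pytest.approx(betweenness_centrality(net))
        assert dict(table["CC"]) == pytest.approx(closeness_centrality(net))
        assert dict(table["EC"]) == pytest.approx(eigenvector_centrality(net))
        assert dict(table["NC"]) == pytest.approx(network_centrality(net))
        assert dict(table["LAC"]) == pytest.approx(local_avg_connectivity(net))

    def test_tsv_round_trip(self, k4, tmp_path):
        table = compute_all(k4)
        table.write_tsv(tmp_path / "t.tsv")
        again = CentralityTable.read_tsv(tmp_path / "t.tsv")
        assert np.allclose(again.frame.values, table.frame.values)
        assert list(again.frame.index) == list(table.frame.index)


@pytest.mark.parametrize("seed", range(8))
def test_all_measures_match_oracles_on_er(seed):
    """Cross-check every measure against an independent brute-force route."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(15, 45))
    g = oracle.connected_er(n, 3.0 / n + 0.08, seed=seed)
    net = net_from_nx(g)
    gg = net.graph
    assert betweenness_centrality(net) == pytest.approx(oracle.betweenness_oracle(gg), abs=1e-9)
    assert closeness_centrality(net) == pytest.approx(oracle.closeness_oracle(gg))
    assert eigenvector_centrality(net) == pytest.approx(oracle.eigenvector_oracle(gg), abs=1e-6)
    assert network_centrality(net) == pytest.approx(oracle.nc_oracle(gg))
    assert local_avg_connectivity(net) == pytest.approx(oracle.lac_oracle(gg))
    assert degree_centrality(net) == {v: gg.degree[v] for v in gg}


def test_relabeling_invariance():
    g = oracle.connected_er(25, 0.15, seed=11)
    net1 = net_from_nx(g)
    mapping = {f"N{v}": f"X{v + 100}" for v in g}
    net2 = Network(graph=nx.relabel_nodes(net1.graph, mapping))
    t1, t2 = compute_all(net1).frame, compute_all(net2).frame
    for old, new in mapping.items():
        assert tuple(t1.loc[old]) == pytest.approx(tuple(t2.loc[new]))


def test_bc_cc_per_component_equals_whole_graph():
    a = nx.gnp_random_graph(20, 0.2, seed=1)
    b = nx.relabel_nodes(nx.gnp_random_graph(15, 0.25, seed=2), {v: v + 100 for v in range(15)})
    whole = net_from_nx(nx.union(a, b))
    bc_whole = betweenness_centrality(whole)
    cc_whole = closeness_centrality(whole)
    for part in (a, b):
        sub = net_from_nx(part)
        for v, val in betweenness_centrality(sub).items():
            assert bc_whole[v] == pytest.approx(val)
        for v, val in closeness_centrality(sub).items():
            assert cc_whole[v] == pytest.approx(val)


class TestMedians:
    def test_odd_and_even_rules(self):
        import pandas as pd

        def table_with_dc(vals):
            frame = pd.DataFrame({m: vals if m == "DC" else [0.0] * len(vals) for m in MEASURES})
            return CentralityTable(frame=frame)

        assert column_medians(table_with_dc([1, 3, 2]))["DC"] == 2
        assert column_medians(table_with_dc([1, 2, 3, 4]))["DC"] == 2.5

    def test_matches_sort_oracle_on_random_columns(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 30))
            frame = pd.DataFrame(rng.uniform(0, 100, size=(n, 6)), columns=list(MEASURES))
            med = column_medians(CentralityTable(frame=frame))
            for m in MEASURES:
                vals = sorted(frame[m])
                expect = vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
                assert med[m] == pytest.approx(expect)

    def test_empty_table_raises(self):
        import pandas as pd

        empty = CentralityTable(frame=pd.DataFrame(columns=list(MEASURES), dtype=float))
        with pytest.raises(ValueError):
            column_medians(empty)
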