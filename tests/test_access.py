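"""Network accessibility: snapping, linear decay, activity periods."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from screenscape.access import (StreetNetwork, access_panel, access_score,
                                access_node_table, snap_to_node)


def line_network(n=7, spacing=1000.0):
    """Nodes 0..n-1 on a line, consecutive edges of `spacing` metres."""
    nodes = pd.DataFrame({"node_id": np.arange(n),
                          "x": np.arange(n) * spacing, "y": 0.0})
    edges = pd.DataFrame({"u": np.arange(n - 1), "v": np.arange(1, n),
                          "length": spacing})
    return StreetNetwork(nodes=nodes, edges=edges)


def centers_at(nodes_xy, first=2004, last=2020):
    return pd.DataFrame({
        "center_id": np.arange(len(nodes_xy)),
        "x": [p[0] for p in nodes_xy], "y": [p[1] for p in nodes_xy],
        "first_active_period": first, "last_active_period": last})


class TestSnap:
    def test_coincident_point(self):
        net = line_network()
        assert snap_to_node((2000.0, 0.0), net) == 2

    def test_equidistant_tie_prefers_smaller_id(self):
        net = line_network()
        assert snap_to_node((500.0, 0.0), net) == 0

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(0)
        nodes = pd.DataFrame({"node_id": np.arange(40),
                              "x": rng.random(40) * 100,
                              "y": rng.random(40) * 100})
        edges = pd.DataFrame({"u": [0], "v": [1], "length": [1.0]})
        net = StreetNetwork(nodes=nodes, edges=edges)
        pts = rng.random((25, 2)) * 100
        got = snap_to_node(pts, net)
        for p, g in zip(pts, got):
            d = np.hypot(nodes["x"] - p[0], nodes["y"] - p[1])
            assert d[g] == pytest.approx(d.min())

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="no nodes"):
            StreetNetwork(nodes=pd.DataFrame(columns=["node_id", "x", "y"]),
                          edges=pd.DataFrame(columns=["u", "v", "length"]))


class TestScore:
    def test_center_at_query_node_scores_one(self):
        net = line_network()
        assert access_score((0.0, 0.0), centers_at([(0.0, 0.0)]), net) == 1.0

    def test_center_at_radius_contributes_zero(self):
        net = line_network(n=7, spacing=1000.0)
        c = centers_at([(5000.0, 0.0)])
        assert access_score((0.0, 0.0), c, net, radius=5000.0) == 0.0

    def test_two_centers_linear_decay_sums_to_one(self):
        """Centers at 1000 m and 4000 m on a 5000-m radius: 0.8 + 0.2."""
        net = line_network(n=7, spacing=1000.0)
        c = centers_at([(1000.0, 0.0), (4000.0, 0.0)])
        assert access_score((0.0, 0.0), c, net) == pytest.approx(1.0)

    def test_additivity_over_disjoint_center_sets(self):
        net = line_network()
        a = centers_at([(1000.0, 0.0)])
        b = centers_at([(3000.0, 0.0)])
        both = pd.concat([a, b], ignore_index=True)
        s = access_score((0.0, 0.0), both, net)
        assert s == pytest.approx(access_score((0.0, 0.0), a, net)
                                  + access_score((0.0, 0.0), b, net))

    def test_radius_monotonicity(self):
        net = line_network()
        c = centers_at([(2000.0, 0.0), (4000.0, 0.0)])
        scores = [access_score((0.0, 0.0), c, net, radius=r)
                  for r in (2500.0, 5000.0, 10000.0)]
        assert scores == sorted(scores)

    def test_unreachable_center_counts_zero(self):
        nodes = pd.DataFrame({"node_id": [0, 1, 2], "x": [0.0, 1000.0, 9e5],
                              "y": 0.0})
        edges = pd.DataFrame({"u": [0], "v": [1], "length": [1000.0]})
        net = StreetNetwork(nodes=nodes, edges=edges)
        c = centers_at([(9e5, 0.0)])  # snaps to isolated node 2
        assert access_score((0.0, 0.0), c, net) == 0.0


class TestPanel:
    def test_activity_interval_respected(self):
        net = line_network()
        c = centers_at([(0.0, 0.0)], first=2008, last=2012)
        pts = pd.DataFrame({"neighborhood_id": [0], "x": [0.0], "y": [0.0]})
        out = access_panel(pts, c, net, range(2004, 2021, 2))
        by_period = out.set_index("period")["access"]
        active = [2008, 2010, 2012]
        assert (by_period.loc[active] == 1.0).all()
        assert (by_period.drop(active) == 0.0).all()

    def test_closure_before_opening_rejected(self):
        net = line_network()
        c = centers_at([(0.0, 0.0)], first=2012, last=2008)
        with pytest.raises(ValueError, match="closes before"):
            access_node_table(net, c, [2008])

    def test_adding_a_center_never_decreases_scores(self):
        net = line_network()
        pts = pd.DataFrame({"neighborhood_id": np.arange(7),
                            "x": np.arange(7) * 1000.0, "y": 0.0})
        base = access_panel(pts, centers_at([(2000.0, 0.0)]), net, [2004])
        more = access_panel(pts, centers_at([(2000.0, 0.0), (5000.0, 0.0)]),
                            net, [2004])
        assert (more["access"] >= base["access"] - 1e-12).all()

    def test_matches_networkx_dijkstra_oracle(self):
        rng = np.random.default_rng(5)
        n = 30
        nodes = pd.DataFrame({"node_id": np.arange(n),
                              "x": rng.random(n) * 4000,
                              "y": rng.random(n) * 4000})
        g = nx.random_geometric_graph(n, 0.45, seed=2,
                                      pos={i: (nodes.x[i] / 4000, nodes.y[i] / 4000)
                                           for i in range(n)})
        edges = pd.DataFrame(
            [(u, v, float(np.hypot(nodes.x[u] - nodes.x[v],
                                   nodes.y[u] - nodes.y[v])))
             for u, v in g.edges], columns=["u", "v", "length"])
        net = StreetNetwork(nodes=nodes, edges=edges)
        centers = centers_at([(nodes.x[3], nodes.y[3]), (nodes.x[17], nodes.y[17])])
        pts = nodes.rename(columns={"node_id": "neighborhood_id"})
        got = access_panel(pts[["neighborhood_id", "x", "y"]], centers, net,
                           [2004], radius=5000.0)

        gnx = nx.Graph()
        for _, r in edges.iterrows():
            gnx.add_edge(int(r.u), int(r.v), weight=r.length)
        for _, row in got.iterrows():
            expected = 0.0
            for cnode in (3, 17):
                try:
                    d = nx.dijkstra_path_length(gnx, int(row.neighborhood_id),
                                                cnode)
                except nx.NetworkXNoPath:
                    continue
                if d <= 5000.0:
                    expected += 1.0 - d / 5000.0
            assert row.access == pytest.approx(expected, abs=1e-9)

    def test_network_distance_bounded_below_by_euclidean(self, small_canton):
        from scipy.sparse.csgraph import dijkstra
        net = small_canton.network
        g = net.adjacency()
        d = dijkstra(g, directed=False, indices=[0])[0]
        xy = net.coords
        eu = np.hypot(xy[:, 0] - xy[0, 0], xy[:, 1] - xy[0, 1])
        finite = np.isfinite(d)
        assert (d[finite] >= eu[finite] - 1e-9).all()
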