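"""Street-network accessibility to screening centers with linear decay.

Accessibility at a point is the sum, over the screening centers active in a
period and reachable within 5000 m of street-network shortest-path distance,
of the weight (1 − d/5000): a center at the doorstep counts 1, a center at
the edge of the radius counts 0.  Query points and centers are snapped to
their nearest network node; center openings and closings make the score
period-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "StreetNetwork",
    "snap_to_node",
    "access_score",
    "access_node_table",
    "access_panel",
]

DEFAULT_RADIUS = 5000.0


@dataclass
class StreetNetwork:
    """Undirected street graph with planar node coordinates and edge lengths.

    ``nodes``: DataFrame with columns node_id, x, y (metres).
    ``edges``: DataFrame with columns u, v, length (metres, > 0).
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.nodes) == 0:
            raise ValueError("street network has no nodes")
        if (self.edges["length"] <= 0).any():
            raise ValueError("edge lengths must be positive")
        self._ids = self.nodes["node_id"].to_numpy()
        self._pos = {int(i): j for j, i in enumerate(self._ids)}
        self._xy = self.nodes[["x", "y"]].to_numpy(dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return self._xy

    def adjacency(self):
        n = len(self._ids)
        u = np.fromiter((self._pos[int(a)] for a in self.edges["u"]), dtype=int,
                        count=len(self.edges))
        v = np.fromiter((self._pos[int(b)] for b in self.edges["v"]), dtype=int,
                        count=len(self.edges))
        w = self.edges["length"].to_numpy(dtype=float)
        m = coo_matrix((np.concatenate([w, w]),
                        (np.concatenate([u, v]), np.concatenate([v, u]))),
                       shape=(n, n))
        return m.tocsr()

    def node_index(self, node_id: int) -> int:
        return self._pos[int(node_id)]


def snap_to_node(points: np.ndarray, network: StreetNetwork) -> np.ndarray:
    """Nearest network node per point, ties broken toward the smallest id.

    Accepts a single (x, y) pair or an (m, 2) array; returns node ids.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    xy = network.coords
    order = np.argsort(network._ids, kind="stable")
    out = np.empty(len(pts), dtype=network._ids.dtype)
    block = max(1, int(2**22 // max(len(xy), 1)))
    for start in range(0, len(pts), block):
        stop = min(start + block, len(pts))
        d2 = ((pts[start:stop, None, :] - xy[None, order, :]) ** 2).sum(axis=2)
        # argmin over id-sorted columns: first minimum = smallest node id
        out[start:stop] = network._ids[order[np.argmin(d2, axis=1)]]
    return out if np.ndim(points) > 1 else out[:1][0]


def _center_node_distances(network: StreetNetwork, centers: pd.DataFrame,
                           radius: float) -> np.ndarray:
    """(n_centers, n_nodes) network distances from snapped center nodes."""
    graph = network.adjacency()
    cnodes = snap_to_node(centers[["x", "y"]].to_numpy(), network)
    idx = np.array([network.node_index(c) for c in np.atleast_1d(cnodes)])
    return dijkstra(graph, directed=False, indices=idx, limit=radius)


def _decay(dist: np.ndarray, radius: float) -> np.ndarray:
    w = 1.0 - dist / radius
    return np.where(np.isfinite(dist) & (dist <= radius), np.maximum(w, 0.0), 0.0)


def access_score(point, centers: pd.DataFrame, network: StreetNetwork,
                 radius: float = DEFAULT_RADIUS) -> float:
    """Linear-decay accessibility of one point to a set of (active) centers.

    score = Σ_centers (1 − d/radius) over centers with network shortest-path
    distance d ≤ radius; unreachable or out-of-range centers contribute 0.
    """
    if len(centers) == 0:
        return 0.0
    dists = _center_node_distances(network, centers, radius)
    node = snap_to_node(np.asarray(point, dtype=float), network)
    j = network.node_index(int(node))
    return float(_decay(dists[:, j], radius).sum())


def _active(centers: pd.DataFrame, period) -> pd.DataFrame:
    bad = centers["last_active_period"] < centers["first_active_period"]
    if bad.any():
        raise ValueError("center closes before it opens: "
                         f"ids {centers.loc[bad, 'center_id'].tolist()}")
    sel = ((centers["first_active_period"] <= period)
           & (centers["last_active_period"] >= period))
    return centers[sel]


def access_node_table(network: StreetNetwork, centers: pd.DataFrame,
                      period_labels, radius: float = DEFAULT_RADIUS) -> pd.DataFrame:
    """Accessibility of every network node in every period.

    Returns a DataFrame indexed by node_id with one column per period label.
    Used both to score individual addresses (via their snapped node) and as
    the backbone of the neighborhood-level panel.
    """
    dists = _center_node_distances(network, centers, radius)
    decayed = _decay(dists, radius)  # (n_centers, n_nodes)
    cols = {}
    for period in period_labels:
        act = _active(centers, period).index
        rows = [centers.index.get_loc(i) for i in act]
        cols[period] = decayed[rows].sum(axis=0) if rows else np.zeros(decayed.shape[1])
    return pd.DataFrame(cols, index=pd.Index(network._ids, name="node_id"))


def access_panel(points: pd.DataFrame, centers: pd.DataFrame,
                 network: StreetNetwork, period_labels,
                 radius: float = DEFAULT_RADIUS) -> pd.DataFrame:
    """Per-point, per-period accessibility scores.

    ``points`` needs an id column (first column) plus x, y.  Returns a long
    DataFrame: id column, period, access.
    """
    id_col = points.columns[0]
    table = access_node_table(network, centers, period_labels, radius=radius)
    nodes = snap_to_node(points[["x", "y"]].to_numpy(), network)
    rows = []
    for period in period_labels:
        scores = table.loc[np.atleast_1d(nodes), period].to_numpy()
        rows.append(pd.DataFrame({id_col: points[id_col].to_numpy(),
                                  "period": period, "access": scores}))
    return pd.concat(rows, ignore_index=True)
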