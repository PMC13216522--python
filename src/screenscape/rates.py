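"""Neighborhood × biennial-period participation rates with SEBS smoothing.

Invitations are consolidated into two-year periods labelled by the even year
(2003 and 2004 both map to "2004"), assigned to the nearest inhabited
neighborhood, and aggregated to counts.  The raw participation rate is
participants / invitations × 100.  Because small neighborhoods produce
unstable rates, spatial empirical Bayes smoothing (SEBS) shrinks each rate
toward a local reference rate estimated from the unit and its 8 nearest
neighbours, with shrinkage weight driven by the local variance and the unit's
own invitation count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .hotspots import build_knn

__all__ = [
    "assign_period",
    "assign_neighborhood",
    "aggregate",
    "sebs_smooth",
    "build_panel",
    "AGE_GROUPS",
]

AGE_GROUPS = ("50-54", "55-59", "60-64", "65-69", "70-74")


def assign_period(year, period_labels) -> np.ndarray:
    """Map invitation years to even-year biennial labels.

    An odd year belongs to the following even year (2003 → "2004"); an even
    year is its own label.  Years mapping outside ``period_labels`` get -1
    (excluded upstream with a logged count).
    """
    year = np.asarray(year, dtype=int)
    labels = np.where(year % 2 == 0, year, year + 1)
    valid = np.isin(labels, np.asarray(list(period_labels), dtype=int))
    return np.where(valid, labels, -1)


def assign_neighborhood(points: np.ndarray, polygons, rng_seed: int = 0,
                        ids: np.ndarray | None = None) -> np.ndarray:
    """Assign points to neighborhoods: containment, else nearest boundary.

    A point inside exactly one polygon gets that polygon's id.  A point
    outside every polygon is assigned to the nearest polygon by boundary
    distance.  A point on a shared boundary (or exactly equidistant from
    several nearest polygons) is assigned uniformly at random among the tied
    candidates, seeded for reproducibility.

    Parameters
    ----------
    points : (m, 2) planar coordinates.
    polygons : sequence of shapely polygons, position-aligned with ``ids``
        (defaults to 0..n-1).
    """
    pts = np.asarray(points, dtype=float)
    geoms = np.asarray(polygons, dtype=object)
    for g in geoms:
        if not g.is_valid:
            raise ValueError(f"invalid neighborhood geometry: {g.wkt[:60]}...")
    ids = np.arange(len(geoms)) if ids is None else np.asarray(ids)
    rng = np.random.default_rng(rng_seed)
    tree = STRtree(geoms)
    pgeoms = shapely.points(pts[:, 0], pts[:, 1])
    out = np.full(len(pts), -1, dtype=ids.dtype)

    # covers() (not contains) so boundary points count as candidates
    pairs = tree.query(pgeoms, predicate="covered_by")
    if pairs.size:
        by_point: dict[int, list[int]] = {}
        for pi, gi in zip(*pairs):
            by_point.setdefault(int(pi), []).append(int(gi))
        for pi, cands in by_point.items():
            choice = cands[0] if len(cands) == 1 else int(rng.choice(sorted(cands)))
            out[pi] = ids[choice]

    unmatched = np.flatnonzero(out == -1)
    for pi in unmatched:
        near, dist = tree.query_nearest(pgeoms[pi], return_distance=True,
                                        all_matches=True)
        cands = sorted(int(g) for g in np.atleast_1d(near))
        choice = cands[0] if len(cands) == 1 else int(rng.choice(cands))
        out[pi] = ids[choice]
    return out


def aggregate(invitations: pd.DataFrame) -> pd.DataFrame:
    """Aggregate assigned invitations to neighborhood × period counts.

    Expects columns ``neighborhood_id``, ``period``, ``participated``.
    Cells with zero invitations are simply absent from the output (missing,
    never zero-rate).  Row order of the input is irrelevant.

    Returns a panel with columns neighborhood_id, period, n, o, raw_rate
    (percent).
    """
    part = invitations["participated"].to_numpy()
    if not np.isin(part, (0, 1)).all():
        raise ValueError("participated must be 0/1")
    g = (invitations.groupby(["neighborhood_id", "period"], sort=True)
         .agg(n=("participated", "size"), o=("participated", "sum"))
         .reset_index())
    g["raw_rate"] = 100.0 * g["o"] / g["n"]
    return g


def _sebs_one_period(n: np.ndarray, o: np.ndarray,
                     windows: np.ndarray) -> np.ndarray:
    """Locally weighted empirical Bayes shrinkage on the proportion scale.

    For window J_i (unit + its k nearest present neighbours):
      m_i = Σ_{j∈J} o_j / Σ_{j∈J} n_j                       local reference
      v_i = Σ_{j∈J} n_j (r_j − m_i)² / Σ_{j∈J} n_j − m_i/(Σ n_j/|J|)
      w_i = v_i / (v_i + m_i/n_i)   with v_i floored at 0
      θ_i = m_i + w_i (r_i − m_i)
    """
    r = o / n
    nw = n[windows]
    ow = o[windows]
    rw = r[windows]
    sn = nw.sum(axis=1)
    m = ow.sum(axis=1) / sn
    nbar = sn / windows.shape[1]
    v = (nw * (rw - m[:, None]) ** 2).sum(axis=1) / sn - m / nbar
    v = np.maximum(v, 0.0)
    denom = v + m / n
    w = np.divide(v, denom, out=np.zeros_like(v), where=denom > 0)
    return m + w * (r - m)


def sebs_smooth(panel: pd.DataFrame, centroids: pd.DataFrame,
                k: int = 8) -> pd.DataFrame:
    """Spatial empirical Bayes smoothing of the panel, period by period.

    KNN windows are rebuilt within each period on the centroids of the units
    actually observed there, so a unit missing from a period never leaks into
    its neighbours' windows.  Adds a ``sebs_rate`` column (percent).  θ always
    lies between the raw rate and the local reference rate.
    """
    cent = centroids.set_index("neighborhood_id")
    out = []
    for period, grp in sorted(panel.groupby("period")):
        grp = grp.sort_values("neighborhood_id").reset_index(drop=True)
        ids = grp["neighborhood_id"].to_numpy()
        n = grp["n"].to_numpy(dtype=float)
        o = grp["o"].to_numpy(dtype=float)
        if len(grp) <= k:
            # too few observed units for a k-window: shrink to pooled rate
            theta = np.full(len(grp), o.sum() / n.sum())
        else:
            w = build_knn(cent.loc[ids, ["x", "y"]].to_numpy(), k=k)
            windows = np.concatenate(
                [np.arange(len(grp))[:, None], w.neighbors], axis=1)
            theta = _sebs_one_period(n, o, windows)
        grp = grp.copy()
        grp["sebs_rate"] = 100.0 * theta
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def build_panel(invitations: pd.DataFrame, neighborhoods: pd.DataFrame,
                period_labels, k: int = 8,
                rng_seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Full rate-construction stage: period + neighborhood assignment,
    aggregation, and SEBS smoothing.

    ``invitations`` needs columns woman_id, invitation_year, participated,
    x, y.  ``neighborhoods`` needs neighborhood_id, polygon (shapely), and
    centroid x, y columns.  Returns the smoothed panel and a small stats dict
    (rows in/out, excluded-year count) for the run manifest.
    """
    inv = invitations.copy()
    inv["period"] = assign_period(inv["invitation_year"], period_labels)
    n_excluded = int((inv["period"] == -1).sum())
    inv = inv[inv["period"] != -1]
    inv["neighborhood_id"] = assign_neighborhood(
        inv[["x", "y"]].to_numpy(), neighborhoods["polygon"].to_list(),
        rng_seed=rng_seed, ids=neighborhoods["neighborhood_id"].to_numpy())
    panel = aggregate(inv)
    cent = neighborhoods[["neighborhood_id", "x", "y"]]
    panel = sebs_smooth(panel, cent, k=k)
    stats = {"rows_in": len(invitations), "rows_used": len(inv),
             "excluded_out_of_window": n_excluded}
    return panel, stats
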