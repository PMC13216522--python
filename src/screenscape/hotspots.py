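"""Getis-Ord Gi* hot/cold spot detection with KNN binary weights.

The Gi* statistic asks, for every spatial unit, whether the values in its
local window (the unit itself plus its k nearest neighbours by centroid
distance) are higher or lower than expected under the global mean.  Inference
is by conditional Monte-Carlo permutation: the focal value stays fixed while
the remaining values are shuffled among the other units, and the pseudo
p-value is the fraction of permuted statistics at least as extreme (in
absolute value) as the observed one, with the usual (m+1)/(M+1) correction so
p is never zero.  Significance is reported in graduated tiers
(p < 0.001, 0.01, 0.05, 0.1), signed hot/cold by the z-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KNNWeights",
    "GiStarResult",
    "build_knn",
    "gi_star",
    "permutation_p",
    "classify_significance",
    "hotspot_analysis",
    "SIGNIFICANCE_TIERS",
]

#: graduated significance thresholds, most stringent first
SIGNIFICANCE_TIERS = (0.001, 0.01, 0.05, 0.1)


class DegenerateSurfaceError(ValueError):
    """Raised when the value surface has zero variance (no pattern possible)."""


@dataclass(frozen=True)
class KNNWeights:
    """Binary k-nearest-neighbour spatial weights.

    ``neighbors[i]`` holds the k unit indices nearest to unit ``i`` by
    centroid Euclidean distance, excluding ``i`` itself.  When
    ``include_self`` is true (the Gi* "star" convention) the focal unit is
    added to its own window with weight 1 at evaluation time.
    """

    k: int
    neighbors: np.ndarray  # (n, k) int array
    include_self: bool = True
    ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.neighbors.shape[0]

    def window(self, i: int) -> np.ndarray:
        """Indices in unit i's local window (self first when included)."""
        if self.include_self:
            return np.concatenate(([i], self.neighbors[i]))
        return self.neighbors[i]


@dataclass
class GiStarResult:
    """Per-unit Gi* z-scores, permutation pseudo-p-values and classes."""

    z: np.ndarray
    pseudo_p: np.ndarray
    classes: np.ndarray  # strings like "hot (p<0.01)" / "not significant"
    degenerate: bool = False
    ids: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = self.ids if self.ids is not None else np.arange(len(self.z))
        return pd.DataFrame(
            {"id": idx, "z": self.z, "pseudo_p": self.pseudo_p, "class": self.classes}
        )


def build_knn(centroids: np.ndarray, k: int, ids: np.ndarray | None = None,
              include_self: bool = True) -> KNNWeights:
    """Build binary KNN weights on centroid coordinates.

    Distance ties are broken by unit order (smallest index wins), which makes
    the neighbour lists fully deterministic.

    Parameters
    ----------
    centroids : (n, 2) array of planar coordinates in metres.
    k : number of neighbours, ``1 <= k < n``.
    """
    pts = np.asarray(centroids, dtype=float)
    n = pts.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n units; got k={k}, n={n}")
    # exact all-pairs search: deterministic tie-breaking by (distance, index)
    neighbors = np.empty((n, k), dtype=np.intp)
    # block the distance matrix to bound memory at ~n*block floats
    block = max(1, int(2**22 // max(n, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        d2 = ((pts[start:stop, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf
        # stable argsort on distance preserves index order among ties
        order = np.argsort(d2, axis=1, kind="stable")
        neighbors[start:stop] = order[:, :k]
    return KNNWeights(k=k, neighbors=neighbors, include_self=include_self,
                      ids=None if ids is None else np.asarray(ids))


def _window_sums(x: np.ndarray, w: KNNWeights) -> tuple[np.ndarray, float]:
    """Local window sums Σ_j w_ij x_j and the (constant) row sum W_i."""
    local = x[w.neighbors].sum(axis=1)
    wi = float(w.k)
    if w.include_self:
        local = local + x
        wi += 1.0
    return local, wi


def gi_star(x: np.ndarray, w: KNNWeights) -> np.ndarray:
    """Getis-Ord Gi* z-scores under binary self-included KNN weights.

    z_i = [Σ_j w_ij x_j − x̄ W_i] / (S · sqrt[(n Σ_j w_ij² − W_i²)/(n−1)])

    where x̄ and S are the global mean and population standard deviation of
    the full surface (focal unit included) and W_i = Σ_j w_ij.  For binary
    weights Σ_j w_ij² = W_i.

    Raises
    ------
    DegenerateSurfaceError
        if the surface is constant (zero global variance).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n != w.n:
        raise ValueError("value vector length does not match weights")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite; drop missing units first")
    xbar = x.mean()
    s = x.std()  # population sd
    if s == 0.0:
        raise DegenerateSurfaceError("constant surface: Gi* undefined")
    local, wi = _window_sums(x, w)
    denom = s * np.sqrt((n * wi - wi**2) / (n - 1))
    return (local - xbar * wi) / denom


def _permutation_table(n_others: int, k: int, n_perm: int,
                       rng: np.random.Generator) -> np.ndarray:
    """(n_perm, k) indices into each unit's "other values" array.

    One table of without-replacement draws from ``range(n_others)`` is shared
    across all focal units (the standard conditional-randomisation shortcut:
    each unit interprets the indices against its own complement vector).
    """
    u = rng.random((n_perm, n_others))
    return np.argsort(u, axis=1, kind="stable")[:, :k]


def permutation_p(x: np.ndarray, w: KNNWeights, n_perm: int = 9999,
                  rng_seed: int = 0) -> np.ndarray:
    """Conditional-permutation pseudo p-values for Gi*.

    The focal value is held fixed; its window is refilled with k values drawn
    without replacement from the other n−1 units.  pseudo_p =
    (#{|z_perm| ≥ |z_obs|} + 1)/(n_perm + 1): a two-sided exceedance count,
    with the direction of the pattern read from the sign of the observed z.
    Deterministic given ``rng_seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    x = np.asarray(x, dtype=float)
    n = x.size
    z_obs = gi_star(x, w)
    rng = np.random.default_rng(rng_seed)
    table = _permutation_table(n - 1, w.k, n_perm, rng)
    xbar = x.mean()
    s = x.std()
    wi = float(w.k) + (1.0 if w.include_self else 0.0)
    denom = s * np.sqrt((n * wi - wi**2) / (n - 1))
    exceed = np.empty(n, dtype=np.int64)
    all_idx = np.arange(n)
    for i in range(n):
        others = x[all_idx != i]
        local_perm = others[table].sum(axis=1)
        if w.include_self:
            local_perm = local_perm + x[i]
        z_perm = (local_perm - xbar * wi) / denom
        exceed[i] = int(np.count_nonzero(np.abs(z_perm) >= abs(z_obs[i])))
    return (exceed + 1.0) / (n_perm + 1.0)


def classify_significance(z: np.ndarray, pseudo_p: np.ndarray) -> np.ndarray:
    """Graduated hot/cold classes from signed z and pseudo-p.

    Records the smallest crossed threshold among 0.001/0.01/0.05/0.1;
    anything else is "not significant".
    """
    z = np.asarray(z, dtype=float)
    p = np.asarray(pseudo_p, dtype=float)
    out = np.full(z.shape, "not significant", dtype=object)
    for thr in SIGNIFICANCE_TIERS[::-1]:  # coarse to fine so fine overwrites
        hot = (z > 0) & (p < thr)
        cold = (z < 0) & (p < thr)
        out[hot] = f"hot (p<{thr})"
        out[cold] = f"cold (p<{thr})"
    return out.astype(str)


def hotspot_analysis(panel: pd.DataFrame, centroids: pd.DataFrame,
                     value_col: str = "sebs_rate", k: int = 16,
                     n_perm: int = 9999, rng_seed: int = 0) -> pd.DataFrame:
    """Cross-sectional Gi* per biennial period.

    Units missing a rate in a period are dropped from that cross-section and
    the KNN weights are rebuilt on the remaining centroids, so every retained
    unit keeps exactly k neighbours.

    Parameters
    ----------
    panel : long table with columns neighborhood_id, period and ``value_col``.
    centroids : table with columns neighborhood_id, x, y.

    Returns
    -------
    long DataFrame: neighborhood_id, period, z, pseudo_p, class.
    """
    cent = centroids.set_index("neighborhood_id")
    frames = []
    for j, (period, grp) in enumerate(sorted(panel.groupby("period"))):
        grp = grp.dropna(subset=[value_col]).sort_values("neighborhood_id")
        ids = grp["neighborhood_id"].to_numpy()
        xy = cent.loc[ids, ["x", "y"]].to_numpy()
        x = grp[value_col].to_numpy(dtype=float)
        w = build_knn(xy, k=k)
        try:
            z = gi_star(x, w)
        except DegenerateSurfaceError:
            frames.append(pd.DataFrame({
                "neighborhood_id": ids, "period": period,
                "z": np.nan, "pseudo_p": np.nan, "class": "no pattern"}))
            continue
        p = permutation_p(x, w, n_perm=n_perm, rng_seed=rng_seed + j)
        frames.append(pd.DataFrame({
            "neighborhood_id": ids, "period": period, "z": z,
            "pseudo_p": p, "class": classify_significance(z, p)}))
    return pd.concat(frames, ignore_index=True)
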