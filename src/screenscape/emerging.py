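"""Emerging hot spot analysis (space-time pattern mining).

The smoothed rate panel becomes a space-time cube: one bin per
(neighborhood, biennial period).  Every bin is scored with the Getis-Ord Gi*
statistic over a spatiotemporal window (the location's spatial KNN plus the
adjacent time steps), p-values are corrected jointly with Benjamini-Hochberg
FDR, a Mann-Kendall test summarises each location's intensity trend, and a
17-category rule table (1 no-pattern + 8 hot + 8 cold) names each location's
temporal pattern of hot/cold membership.  The Historical category uses a 50%
threshold instead of the conventional 90%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .hotspots import build_knn

__all__ = [
    "SpaceTimeCube",
    "build_cube",
    "bin_gi_star",
    "fdr_adjust",
    "mann_kendall",
    "classify_location",
    "ehsa",
    "CATEGORIES",
    "PATTERN_NAMES",
]

PATTERN_NAMES = ("new", "consecutive", "intensifying", "persistent",
                 "diminishing", "sporadic", "oscillating", "historical")

#: the closed 17-label vocabulary
CATEGORIES = (("no_pattern",)
              + tuple(f"{p}_hot" for p in PATTERN_NAMES)
              + tuple(f"{p}_cold" for p in PATTERN_NAMES))


@dataclass
class SpaceTimeCube:
    """Location × period value lattice with a presence mask.

    ``values[i, t]`` is the smoothed rate of location i in period t; bins
    where the location was not observed are masked out, never imputed.
    """

    locations: np.ndarray          # ordered neighborhood ids
    periods: np.ndarray            # ordered even-year labels
    values: np.ndarray             # (L, T) float, NaN where masked
    mask: np.ndarray               # (L, T) bool, True = observed

    @property
    def capacity(self) -> int:
        """Total number of space-time bins, |locations| × |periods|."""
        return int(self.values.shape[0] * self.values.shape[1])

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())


def build_cube(panel: pd.DataFrame, value_col: str = "sebs_rate") -> SpaceTimeCube:
    """Pivot a long panel into a space-time cube.

    Locations and periods are sorted, so the cube is invariant to the row
    order of the panel.  Requires at least two periods.
    """
    periods = np.sort(panel["period"].unique())
    if periods.size < 2:
        raise ValueError("space-time cube needs at least 2 periods")
    wide = panel.pivot_table(index="neighborhood_id", columns="period",
                             values=value_col, aggfunc="first")
    wide = wide.reindex(columns=periods).sort_index()
    values = wide.to_numpy(dtype=float)
    mask = np.isfinite(values)
    return SpaceTimeCube(locations=wide.index.to_numpy(), periods=periods,
                         values=values, mask=mask)


def bin_gi_star(cube: SpaceTimeCube, centroids: pd.DataFrame,
                spatial_k: int = 8, temporal_window: int = 1) -> pd.DataFrame:
    """Gi* z-score and analytic two-sided p for every observed bin.

    The window of bin (i, t) is {i} ∪ spatial-KNN(i) crossed with time steps
    t−temporal_window … t+temporal_window (clipped to the study span).
    Masked bins are excluded from their neighbours' sums, which renormalises
    W_i bin by bin.  The global mean and standard deviation are taken over
    all observed bins of the cube.

    Returns a long DataFrame: neighborhood_id, period, z, p (NaN for masked
    bins).
    """
    cent = centroids.set_index("neighborhood_id")
    xy = cent.loc[cube.locations, ["x", "y"]].to_numpy()
    w = build_knn(xy, k=spatial_k)
    L, T = cube.values.shape
    windows = np.concatenate([np.arange(L)[:, None], w.neighbors], axis=1)

    x = np.where(cube.mask, cube.values, 0.0)
    m = cube.mask.astype(float)
    # spatial window sums per (location, period)
    sx = x[windows].sum(axis=1)      # (L, T)
    sm = m[windows].sum(axis=1)
    # add temporal lags
    lx = np.zeros_like(sx)
    lm = np.zeros_like(sm)
    for lag in range(-temporal_window, temporal_window + 1):
        lo, hi = max(0, -lag), min(T, T - lag)
        lx[:, lo:hi] += sx[:, lo + lag:hi + lag]
        lm[:, lo:hi] += sm[:, lo + lag:hi + lag]

    obs = cube.values[cube.mask]
    n = obs.size
    xbar = obs.mean()
    s = obs.std()
    z = np.full((L, T), np.nan)
    p = np.full((L, T), np.nan)
    if s == 0.0:
        # constant cube: degenerate, everything "neither"
        return _bin_frame(cube, z, p)
    wi = lm  # binary weights: Σw² = W
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = s * np.sqrt((n * wi - wi**2) / (n - 1))
        zz = (lx - xbar * wi) / denom
    z[cube.mask] = zz[cube.mask]
    p[cube.mask] = 2.0 * sps.norm.sf(np.abs(z[cube.mask]))
    return _bin_frame(cube, z, p)


def _bin_frame(cube: SpaceTimeCube, z: np.ndarray, p: np.ndarray) -> pd.DataFrame:
    L, T = z.shape
    return pd.DataFrame({
        "neighborhood_id": np.repeat(cube.locations, T),
        "period": np.tile(cube.periods, L),
        "z": z.ravel(),
        "p": p.ravel(),
    })


def fdr_adjust(bins: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up over all observed bins jointly.

    Adds an ``indicator`` column: "hot" when rejected with z > 0, "cold" when
    rejected with z < 0, otherwise "neither".
    """
    out = bins.copy()
    out["indicator"] = "neither"
    obs = out["p"].notna()
    if obs.any():
        reject, _, _, _ = multipletests(out.loc[obs, "p"], alpha=alpha,
                                        method="fdr_bh")
        zobs = out.loc[obs, "z"].to_numpy()
        ind = np.where(reject & (zobs > 0), "hot",
                       np.where(reject & (zobs < 0), "cold", "neither"))
        out.loc[obs, "indicator"] = ind
    return out


def mann_kendall(series, alpha: float = 0.05) -> dict:
    """Mann-Kendall monotone-trend test with tie correction.

    S = Σ_{i<j} sgn(x_j − x_i);
    Var(S) = [n(n−1)(2n+5) − Σ_ties t(t−1)(2t+5)] / 18;
    z = (S−1)/√Var if S>0, 0 if S=0, (S+1)/√Var if S<0 (continuity
    corrected); p is two-sided normal.  Fewer than 4 observed values, or a
    constant series, yield direction "none".
    """
    x = np.asarray([v for v in series if np.isfinite(v)], dtype=float)
    n = x.size
    if n < 4:
        return {"S": 0, "var_S": np.nan, "z": 0.0, "p": 1.0,
                "direction": "none", "n": n}
    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff, 1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:
        return {"S": s, "var_S": 0.0, "z": 0.0, "p": 1.0,
                "direction": "none", "n": n}
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * sps.norm.sf(abs(z))
    if p < alpha:
        direction = "increasing" if z > 0 else "decreasing"
    else:
        direction = "none"
    return {"S": s, "var_S": float(var_s), "z": float(z), "p": float(p),
            "direction": direction, "n": n}


def _final_run_length(ind: np.ndarray) -> int:
    run = 0
    for v in ind[::-1]:
        if not v:
            break
        run += 1
    return run


def _classify_family(ind: np.ndarray, opp: np.ndarray, trend: str,
                     run_threshold: float, historical_threshold: float) -> str | None:
    """One family (hot or cold) of the rule table, in fixed precedence order.

    ``trend`` is already oriented so that "increasing" means the family's
    intensity is increasing.
    """
    t = ind.size
    frac = ind.sum() / t
    final = bool(ind[-1])
    if final and not ind[:-1].any():
        return "new"
    run = _final_run_length(ind)
    if final and run >= 2 and not ind[:-run].any() and frac < run_threshold:
        return "consecutive"
    if frac >= run_threshold:
        if trend == "increasing":
            return "intensifying"
        if trend == "decreasing":
            return "diminishing"
        return "persistent"
    if final and not opp.any():
        return "sporadic"
    if final and opp[:-1].any():
        return "oscillating"
    if not final and frac >= historical_threshold:
        return "historical"
    return None


def classify_location(hot_series, cold_series, trend_direction: str,
                      run_threshold: float = 0.90,
                      historical_threshold: float = 0.50) -> str:
    """Name a location's spatiotemporal pattern from the 17-label table.

    ``hot_series``/``cold_series`` are the post-FDR bin indicators over the
    location's observed periods; ``trend_direction`` is the Mann-Kendall
    direction of the bin z-scores ("increasing"/"decreasing"/"none").  Hot
    categories are evaluated first (new, consecutive, intensifying,
    persistent, diminishing, sporadic, oscillating, historical); the cold
    family is the mirror image, tried only if no hot label fires — with the
    trend flipped, since an intensifying cold spot is one whose z-score
    trends *downward*.  Anything left is "no_pattern".
    """
    hot = np.asarray(hot_series, dtype=bool)
    cold = np.asarray(cold_series, dtype=bool)
    if hot.shape != cold.shape:
        raise ValueError("hot and cold series must be aligned")
    if (hot & cold).any():
        raise AssertionError("a bin cannot be hot and cold at once")
    if hot.size < 2:
        return "no_pattern"
    lab = _classify_family(hot, cold, trend_direction,
                           run_threshold, historical_threshold)
    if lab is not None:
        return f"{lab}_hot"
    mirror = {"increasing": "decreasing", "decreasing": "increasing"}
    lab = _classify_family(cold, hot, mirror.get(trend_direction, "none"),
                           run_threshold, historical_threshold)
    if lab is not None:
        return f"{lab}_cold"
    return "no_pattern"


def ehsa(panel: pd.DataFrame, centroids: pd.DataFrame,
         value_col: str = "sebs_rate", spatial_k: int = 8,
         temporal_window: int = 1, alpha: float = 0.05,
         alpha_trend: float = 0.05, run_threshold: float = 0.90,
         historical_threshold: float = 0.50) -> dict:
    """Full emerging-hot-spot stage.

    Returns a dict with:

    ``locations``
        per-location DataFrame: neighborhood_id, category, n_hot, n_cold,
        n_observed, mk_S, mk_z, mk_p.
    ``bins``
        per-bin DataFrame with z, p and post-FDR indicator.
    ``category_period_means``
        mean smoothed rate by (category, period) — the trajectory surface.
    ``cube``
        the SpaceTimeCube.
    """
    cube = build_cube(panel, value_col=value_col)
    bins = bin_gi_star(cube, centroids, spatial_k=spatial_k,
                       temporal_window=temporal_window)
    bins = fdr_adjust(bins, alpha=alpha)

    L, T = cube.values.shape
    ind = bins["indicator"].to_numpy().reshape(L, T)
    zmat = bins["z"].to_numpy().reshape(L, T)
    rows = []
    for i, loc in enumerate(cube.locations):
        obs = cube.mask[i]
        hot = (ind[i] == "hot")[obs]
        cold = (ind[i] == "cold")[obs]
        mk = mann_kendall(zmat[i][obs], alpha=alpha_trend)
        cat = classify_location(hot, cold, mk["direction"],
                                run_threshold=run_threshold,
                                historical_threshold=historical_threshold)
        rows.append({"neighborhood_id": loc, "category": cat,
                     "n_hot": int(hot.sum()), "n_cold": int(cold.sum()),
                     "n_observed": int(obs.sum()), "mk_S": mk["S"],
                     "mk_z": mk["z"], "mk_p": mk["p"]})
    locs = pd.DataFrame(rows)
    merged = panel.merge(locs[["neighborhood_id", "category"]],
                         on="neighborhood_id")
    surface = (merged.groupby(["category", "period"])[value_col]
               .mean().reset_index()
               .rename(columns={value_col: "mean_rate"}))
    return {"locations": locs, "bins": bins,
            "category_period_means": surface, "cube": cube}
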