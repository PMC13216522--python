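"""Synthetic canton generator with planted spatiotemporal structure.

Emulates the data layout of an organized breast-cancer-screening program in
a small, dense canton: irregular neighborhood polygons (a Voronoi
tessellation of a square canton), a spatially autocorrelated 0-1 deprivation
index, screening centers concentrated in an urban core with opening/closing
periods, a perturbed-grid street network, a building registry for geocoding,
and a biennial invitation stream for women aged 50-74.  Participation is
Bernoulli on a logit scale:

    logit p = intercept + β_dep · deprivation + β_acc · access + shift(i, t)

where shift(i, t) plants spatial clusters that follow prescribed temporal
trajectories (persistent, intensifying, diminishing, new, sporadic,
historical, and their cold mirrors).  The planted truth is recorded per
neighborhood so downstream hot-spot and determinants stages can be scored
against it.

All randomness flows from ``CantonSpec.rng_seed`` through salted
``numpy.random.SeedSequence`` streams (one per generation concern), so a
given spec is bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi
from scipy.special import expit
from shapely.geometry import Polygon, box

from .access import StreetNetwork, access_node_table, snap_to_node
from .rates import AGE_GROUPS

__all__ = [
    "TRAJECTORIES",
    "PatternPlan",
    "CantonSpec",
    "SyntheticCanton",
    "trajectory_shifts",
    "generate_canton",
    "generate_invitations",
    "simulate",
    "default_spec",
    "full_pattern_spec",
    "determinants_benchmark_spec",
    "generate_registry",
    "perturb_address",
]

TRAJECTORIES = ("none", "persistent_hot", "intensifying_hot",
                "diminishing_hot", "new_hot", "sporadic_hot",
                "historical_hot", "persistent_cold", "intensifying_cold")

# stream salts: one independent substream per generation concern
_SALT = {"geometry": 1, "deprivation": 2, "network": 3, "centers": 4,
         "buildings": 5, "women": 6, "patterns": 7, "invitations": 8,
         "heterogeneity": 9}


def _rng(seed: int, concern: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _SALT[concern]]))


@dataclass(frozen=True)
class PatternPlan:
    """One planted cluster: a region of neighborhoods and its trajectory.

    ``base_shift`` is the log-odds magnitude of the participation shift.  If
    ``region`` is None the generator picks ``size`` mutually nearby
    neighborhoods away from previously planted regions.  Explicit
    ``per_period_shifts`` override the trajectory template.
    """

    trajectory: str
    base_shift: float
    size: int = 13
    region: frozenset | None = None
    per_period_shifts: tuple | None = None

    def __post_init__(self):
        if self.trajectory not in TRAJECTORIES:
            raise ValueError(f"unknown trajectory {self.trajectory!r}; "
                             f"expected one of {TRAJECTORIES}")


def trajectory_shifts(trajectory: str, base_shift: float,
                      n_periods: int) -> np.ndarray:
    """Per-period log-odds shifts implementing a named trajectory.

    Hot trajectories shift participation up, cold down.  Intensifying ramps
    from 0.5× to 1.5× the base magnitude, diminishing is its reverse, new
    fires only in the final period, sporadic alternates on/off ending on,
    historical covers the first ~60% of periods and then stops.
    """
    t = n_periods
    b = abs(base_shift) * (-1.0 if trajectory.endswith("_cold") else 1.0)
    if trajectory == "none":
        return np.zeros(t)
    kind = trajectory.rsplit("_", 1)[0]
    if kind == "persistent":
        return np.full(t, b)
    if kind == "intensifying":
        return np.linspace(0.5 * b, 1.5 * b, t)
    if kind == "diminishing":
        return np.linspace(1.5 * b, 0.5 * b, t)
    if kind == "new":
        out = np.zeros(t)
        out[-1] = 1.25 * b
        return out
    if kind == "sporadic":
        out = np.zeros(t)
        out[t - 1::-2] = b  # on in the final period, alternating backwards
        return out
    if kind == "historical":
        out = np.zeros(t)
        out[:max(1, math.ceil(0.6 * t))] = b
        return out
    raise ValueError(f"unknown trajectory {trajectory!r}")


@dataclass(frozen=True)
class CantonSpec:
    """Full configuration of a synthetic canton.

    Effects are log-odds per unit of the covariate; the intercept may be
    ``-inf`` (degenerate zero-participation canton) but never NaN.
    ``period_labels`` are even years, strictly increasing in steps of two.
    """

    n_neighborhoods: int = 400
    n_women: int = 50000
    period_labels: tuple = tuple(range(2004, 2021, 2))
    deprivation_range: tuple = (0.0, 1.0)
    spatial_autocorr_scale: float = 1500.0
    effect_deprivation: float = 0.15
    effect_access: float = -0.05
    intercept: float = -0.39
    overdispersion_sd: float = 0.9   # log-odds sd of cell-level extra noise
    planted_patterns: tuple = ()
    rng_seed: int = 1
    n_centers: int = 10
    age_range: tuple = (48, 74)   # age at study start; cohort turnover knob
    canton_size: float | None = None   # side of the square canton, metres
    access_radius: float = 5000.0

    @property
    def size(self) -> float:
        if self.canton_size is not None:
            return float(self.canton_size)
        return 600.0 * math.sqrt(self.n_neighborhoods)

    @property
    def n_periods(self) -> int:
        return len(self.period_labels)

    def validate(self) -> None:
        if self.n_neighborhoods < 25:
            raise ValueError("n_neighborhoods: must be at least 25")
        if self.n_women < 1:
            raise ValueError("n_women: must be positive")
        labels = list(self.period_labels)
        if not labels:
            raise ValueError("period_labels: must not be empty")
        if any(int(y) % 2 != 0 for y in labels):
            raise ValueError("period_labels: labels must be even years")
        if any(b - a != 2 for a, b in zip(labels, labels[1:])):
            raise ValueError("period_labels: must increase in steps of 2")
        lo, hi = self.deprivation_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("deprivation_range: must be within [0, 1]")
        for name in ("effect_deprivation", "effect_access"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name}: must be finite")
        if not (np.isfinite(self.overdispersion_sd)
                and self.overdispersion_sd >= 0):
            raise ValueError("overdispersion_sd: must be finite and >= 0")
        if np.isnan(self.intercept):
            raise ValueError("intercept: must not be NaN")
        for plan in self.planted_patterns:
            if plan.per_period_shifts is not None and \
                    len(plan.per_period_shifts) != self.n_periods:
                raise ValueError("planted_patterns: per_period_shifts length "
                                 "must equal the number of periods")
            if plan.trajectory == "none" and plan.per_period_shifts is not None \
                    and any(v != 0 for v in plan.per_period_shifts):
                raise ValueError("planted_patterns: trajectory 'none' "
                                 "requires all shifts 0")


@dataclass
class SyntheticCanton:
    """Generated study region plus its planted truth.

    ``neighborhoods``: neighborhood_id, polygon (shapely), x, y (centroid),
    population, deprivation.  ``truth``: neighborhood_id, trajectory.
    """

    spec: CantonSpec
    neighborhoods: pd.DataFrame
    centers: pd.DataFrame
    network: StreetNetwork
    registry: pd.DataFrame
    women: pd.DataFrame
    truth: pd.DataFrame
    shifts: np.ndarray          # (n_neighborhoods, n_periods) log-odds
    invitations: pd.DataFrame | None = None


# ---------------------------------------------------------------- geometry

def _voronoi_polygons(seeds: np.ndarray, size: float) -> list[Polygon]:
    """Voronoi cells of the seed points clipped to the square canton.

    Seeds are mirrored across the four sides so every interior region is
    finite before clipping.
    """
    refl = [seeds * [1, -1], seeds * [1, -1] + [0, 2 * size],
            seeds * [-1, 1], seeds * [-1, 1] + [2 * size, 0]]
    vor = Voronoi(np.concatenate([seeds] + refl))
    square = box(0.0, 0.0, size, size)
    polys = []
    for i in range(len(seeds)):
        verts = vor.vertices[vor.regions[vor.point_region[i]]]
        center = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - center[1],
                                      verts[:, 0] - center[0]))
        poly = Polygon(verts[order]).intersection(square)
        polys.append(poly)
    return polys


def _sample_in_polygon(poly: Polygon, size: int,
                       rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    out: list[np.ndarray] = []
    have = 0
    while have < size:
        m = max(32, 4 * (size - have))
        cand = rng.uniform((minx, miny), (maxx, maxy), (m, 2))
        keep = cand[shapely.contains_xy(poly, cand[:, 0], cand[:, 1])]
        out.append(keep)
        have += len(keep)
    return np.concatenate(out)[:size]


# ------------------------------------------------------------- street names

_SYLLABLES = ("mon", "ver", "sal", "bel", "cor", "lan", "flo", "ris",
              "tan", "pra", "lu", "mi", "ro", "cha", "ne", "gal",
              "bou", "ter", "vi", "jon", "pe", "mar", "clo", "si")
_STREET_TYPES = ("chemin", "avenue", "rue", "route", "place", "boulevard")
_PARTICLES = ("des", "du", "de la")


def _street_name(idx: int) -> str:
    """Deterministic, globally unique street name for index ``idx``."""
    k = len(_SYLLABLES)
    noun = _SYLLABLES[(idx // k) % k] + _SYLLABLES[idx % k]
    if idx >= k * k:
        noun = _SYLLABLES[(idx // (k * k)) % k] + noun
    stype = _STREET_TYPES[idx % len(_STREET_TYPES)]
    particle = _PARTICLES[(idx // len(_STREET_TYPES)) % len(_PARTICLES)]
    return f"{stype} {particle} {noun}"


# ------------------------------------------------------------------ canton

def generate_canton(spec: CantonSpec) -> SyntheticCanton:
    """Generate the study region, population and infrastructure.

    Deterministic given ``spec.rng_seed``.  The deprivation field is smoothed
    white noise (positive spatial association at
    ``spec.spatial_autocorr_scale``), centers cluster in the canton's urban
    core, and the building registry covers every address later handed to the
    geocoder.
    """
    spec.validate()
    size = spec.size
    n = spec.n_neighborhoods

    rng_geo = _rng(spec.rng_seed, "geometry")
    seeds = rng_geo.uniform(0.0, size, (n, 2))
    polys = _voronoi_polygons(seeds, size)
    cents = np.array([[p.centroid.x, p.centroid.y] for p in polys])

    # deprivation: Gaussian-kernel-smoothed white noise, min-max scaled
    rng_dep = _rng(spec.rng_seed, "deprivation")
    eps = rng_dep.normal(size=n)
    d2 = ((cents[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    kern = np.exp(-d2 / (2.0 * spec.spatial_autocorr_scale**2))
    dep = kern @ eps / kern.sum(axis=1)
    lo, hi = spec.deprivation_range
    dep = lo + (hi - lo) * (dep - dep.min()) / (dep.max() - dep.min())

    # population: denser toward the urban core
    rng_wom = _rng(spec.rng_seed, "women")
    core = np.array([size / 2.0, size / 2.0])
    dist_core = np.hypot(*(cents - core).T)
    wpop = 0.3 + np.exp(-((dist_core / (size / 3.0)) ** 2))
    pop = rng_wom.multinomial(spec.n_women, wpop / wpop.sum())

    # street network: perturbed grid, edge length = Euclidean node distance
    rng_net = _rng(spec.rng_seed, "network")
    m = max(10, int(round(2 * math.sqrt(n))))
    gx, gy = np.meshgrid(np.linspace(0, size, m + 1), np.linspace(0, size, m + 1))
    h = size / m
    nodes_xy = np.column_stack([gx.ravel(), gy.ravel()])
    nodes_xy = nodes_xy + rng_net.uniform(-0.25 * h, 0.25 * h, nodes_xy.shape)
    node_ids = np.arange(len(nodes_xy))
    grid_id = node_ids.reshape(m + 1, m + 1)
    edges = []
    for a, b in [(grid_id[:, :-1].ravel(), grid_id[:, 1:].ravel()),
                 (grid_id[:-1, :].ravel(), grid_id[1:, :].ravel())]:
        edges.append(np.column_stack([a, b]))
    euv = np.concatenate(edges)
    elen = np.hypot(*(nodes_xy[euv[:, 0]] - nodes_xy[euv[:, 1]]).T)
    network = StreetNetwork(
        nodes=pd.DataFrame({"node_id": node_ids,
                            "x": nodes_xy[:, 0], "y": nodes_xy[:, 1]}),
        edges=pd.DataFrame({"u": euv[:, 0], "v": euv[:, 1], "length": elen}))

    # screening centers in the urban core, with opening/closing periods
    rng_cen = _rng(spec.rng_seed, "centers")
    cxy = np.clip(core + rng_cen.normal(scale=size / 5.0, size=(spec.n_centers, 2)),
                  0.02 * size, 0.98 * size)
    labels = list(spec.period_labels)
    first = [labels[0]] * spec.n_centers
    last = [labels[-1]] * spec.n_centers
    n_partial = spec.n_centers // 3 if len(labels) > 2 else 0
    for j in range(n_partial):  # later centers open mid-study or close early
        i = spec.n_centers - 1 - j
        if j % 2 == 0:
            first[i] = labels[int(rng_cen.integers(1, len(labels)))]
        else:
            last[i] = labels[int(rng_cen.integers(0, len(labels) - 1))]
    centers = pd.DataFrame({"center_id": np.arange(spec.n_centers),
                            "x": cxy[:, 0], "y": cxy[:, 1],
                            "first_active_period": first,
                            "last_active_period": last})

    # building registry + women's addresses
    rng_bld = _rng(spec.rng_seed, "buildings")
    g = 4  # postal zones: g × g grid
    reg_rows = []
    women_rows = []
    street_counter = 0
    woman_id = 0
    for i in range(n):
        n_b = max(2, int(math.ceil(pop[i] / 3)))
        pts = _sample_in_polygon(polys[i], n_b, rng_bld)
        n_streets = max(1, n_b // 8)
        postal = str(1200 + int(cents[i, 1] // (size / g)) * g
                     + int(cents[i, 0] // (size / g)))
        b_start = len(reg_rows)
        for b in range(n_b):
            s_local = b % n_streets
            reg_rows.append((_street_name(street_counter + s_local),
                             str(b // n_streets + 1), postal,
                             pts[b, 0], pts[b, 1]))
        street_counter += n_streets
        if pop[i] > 0:
            picks = rng_wom.integers(0, n_b, size=pop[i])
            for b in picks:
                st, num, pc, bx, by = reg_rows[b_start + b]
                women_rows.append((woman_id, i, f"{st} {num}", pc, bx, by))
                woman_id += 1
    registry = pd.DataFrame(reg_rows, columns=["street_name", "street_number",
                                               "postal_code", "x", "y"])
    ages = rng_wom.integers(spec.age_range[0], spec.age_range[1] + 1,
                            size=woman_id)
    women = pd.DataFrame(women_rows, columns=["woman_id", "neighborhood_id",
                                              "address", "postal_code",
                                              "x", "y"])
    women["age_at_start"] = ages

    # planted regions
    rng_pat = _rng(spec.rng_seed, "patterns")
    shifts = np.zeros((n, spec.n_periods))
    truth = np.array(["none"] * n, dtype=object)
    spacing = size / math.sqrt(n)
    used: set[int] = set()
    for plan in spec.planted_patterns:
        if plan.trajectory == "none":
            continue
        if plan.region is not None:
            region = sorted(int(r) for r in plan.region)
        else:
            region = _place_region(cents, plan.size, used, spacing, rng_pat)
        per = (np.asarray(plan.per_period_shifts, dtype=float)
               if plan.per_period_shifts is not None
               else trajectory_shifts(plan.trajectory, plan.base_shift,
                                      spec.n_periods))
        for r in region:
            shifts[r] += per
            truth[r] = plan.trajectory
        used |= set(region)

    neighborhoods = pd.DataFrame({
        "neighborhood_id": np.arange(n), "polygon": polys,
        "x": cents[:, 0], "y": cents[:, 1],
        "population": pop, "deprivation": dep})
    truth_df = pd.DataFrame({"neighborhood_id": np.arange(n),
                             "trajectory": truth})
    return SyntheticCanton(spec=spec, neighborhoods=neighborhoods,
                           centers=centers, network=network,
                           registry=registry, women=women, truth=truth_df,
                           shifts=shifts)


def _place_region(cents: np.ndarray, size: int, used: set[int],
                  spacing: float, rng: np.random.Generator) -> list[int]:
    """Pick a compact set of unused neighborhoods, clear of prior regions."""
    n = len(cents)
    free = np.array(sorted(set(range(n)) - used))
    if len(free) < size:
        raise ValueError("not enough unplanted neighborhoods for pattern")
    for attempt in range(200):
        seed = int(rng.choice(free))
        order = np.argsort(np.hypot(*(cents[free] - cents[seed]).T))
        region = free[order[:size]]
        if not used:
            return [int(r) for r in region]
        # prefer planted cores separated by a couple of rings of
        # neighborhoods; relax the separation if the canton is too small
        uxy = cents[sorted(used)]
        mind = np.sqrt(((uxy[:, None, :] - cents[region][None, :, :]) ** 2)
                       .sum(axis=2)).min()
        sep = 3.0 * spacing * max(0.0, 1.0 - attempt / 100.0)
        if mind > sep:
            return [int(r) for r in region]
    raise ValueError("could not place planted region away from existing ones")


# -------------------------------------------------------------- invitations

def generate_invitations(canton: SyntheticCanton,
                         spec: CantonSpec | None = None) -> pd.DataFrame:
    """Biennial invitation stream with Bernoulli participation.

    Every woman is invited once per biennial period while her age is in
    50-74.  Participation probability is
    expit(intercept + β_dep·deprivation + β_acc·access + planted shift).
    The invitation year is the even label or the preceding odd year, at
    random, so the period-assignment rule is genuinely exercised downstream.
    Women never eligible in any period are excluded (count retained in
    ``df.attrs['n_never_eligible']``).
    """
    spec = canton.spec if spec is None else spec
    rng = _rng(spec.rng_seed, "invitations")
    labels = list(spec.period_labels)
    y0 = labels[0]
    node_access = access_node_table(canton.network, canton.centers, labels,
                                    radius=spec.access_radius)
    wnodes = snap_to_node(canton.women[["x", "y"]].to_numpy(), canton.network)
    wacc = node_access.loc[np.atleast_1d(wnodes)].to_numpy()  # (n_women, T)
    dep = canton.neighborhoods.set_index("neighborhood_id")["deprivation"]
    wdep = dep.loc[canton.women["neighborhood_id"]].to_numpy()
    # transient neighborhood-by-period overdispersion: the extra-binomial
    # noise real small-area rates show, independent across cells so the
    # planted patterns remain the only persistent structure
    rng_het = _rng(spec.rng_seed, "heterogeneity")
    cell_u = rng_het.normal(scale=spec.overdispersion_sd,
                            size=(len(canton.neighborhoods), len(labels))) \
        if spec.overdispersion_sd > 0 else \
        np.zeros((len(canton.neighborhoods), len(labels)))
    wnb = canton.women["neighborhood_id"].to_numpy()
    wshift = canton.shifts[canton.women["neighborhood_id"].to_numpy()]
    age0 = canton.women["age_at_start"].to_numpy()

    frames = []
    ever = np.zeros(len(canton.women), dtype=bool)
    for j, label in enumerate(labels):
        age = age0 + (label - y0)
        elig = (age >= 50) & (age <= 74)
        ever |= elig
        if not elig.any():
            continue
        logit = (spec.intercept + spec.effect_deprivation * wdep[elig]
                 + spec.effect_access * wacc[elig, j]
                 + cell_u[wnb[elig], j] + wshift[elig, j])
        participated = (rng.random(elig.sum()) < expit(logit)).astype(int)
        year = label - rng.integers(0, 2, size=elig.sum())
        band = np.clip((age[elig] - 50) // 5, 0, 4)
        frames.append(pd.DataFrame({
            "woman_id": canton.women.loc[elig, "woman_id"].to_numpy(),
            "invitation_year": year,
            "participated": participated,
            "age_group": np.array(AGE_GROUPS)[band],
            "address": canton.women.loc[elig, "address"].to_numpy(),
            "postal_code": canton.women.loc[elig, "postal_code"].to_numpy(),
            "x": canton.women.loc[elig, "x"].to_numpy(),
            "y": canton.women.loc[elig, "y"].to_numpy(),
            "neighborhood_id": canton.women.loc[elig, "neighborhood_id"].to_numpy(),
            "period": label,
        }))
    inv = pd.concat(frames, ignore_index=True)
    inv.attrs["n_never_eligible"] = int((~ever).sum())
    return inv


def simulate(spec: CantonSpec) -> SyntheticCanton:
    """Generate the canton and its invitation stream in one call."""
    canton = generate_canton(spec)
    canton.invitations = generate_invitations(canton, spec)
    return canton


# ----------------------------------------------------------------- presets

def default_spec(rng_seed: int = 1, n_neighborhoods: int = 400,
                 n_women: int = 50000) -> CantonSpec:
    """The default demo canton: two planted hot cores with known truth.

    Designed as a recoverable-ground-truth benchmark: mild covariate effects
    (deprivation +0.15, access −0.05 log-odds) keep the background close to
    exchangeable, transient cell-level overdispersion (0.9 log-odds sd) keeps
    the empirical Bayes shrinkage partial so smoothing does not manufacture
    spatial correlation, per-cell counts (~115 invitations) keep rates
    informative, and the two planted cores (persistent and intensifying,
    +1.8 log-odds) are strong enough to dominate their local windows.
    """
    return CantonSpec(
        n_neighborhoods=n_neighborhoods, n_women=n_women, rng_seed=rng_seed,
        planted_patterns=(PatternPlan("persistent_hot", 1.8, size=13),
                          PatternPlan("intensifying_hot", 1.8, size=13)))


def full_pattern_spec(rng_seed: int = 1, n_neighborhoods: int = 400,
                      n_women: int = 12000) -> CantonSpec:
    """A canton planting one region per trajectory family (for exploration)."""
    plans = tuple(PatternPlan(t, 1.8, size=10) for t in
                  ("persistent_hot", "intensifying_hot", "diminishing_hot",
                   "new_hot", "sporadic_hot", "historical_hot",
                   "persistent_cold"))
    return CantonSpec(n_neighborhoods=n_neighborhoods, n_women=n_women,
                      rng_seed=rng_seed, planted_patterns=plans)


def determinants_benchmark_spec(rng_seed: int = 1) -> CantonSpec:
    """Single-period canton with dominant covariate effects.

    Used to benchmark the determinants model: deprivation (+1.5 log-odds)
    and accessibility (−0.4 log-odds) dominate the participation surface,
    age composition carries no signal, and with ~70 invitations per
    neighborhood the smoothed rates are informative enough for the model to
    recover the planted structure.
    """
    return CantonSpec(n_neighborhoods=2000, n_women=150000,
                      period_labels=(2020,), effect_deprivation=1.5,
                      effect_access=-0.4, intercept=-0.75,
                      overdispersion_sd=0.1, rng_seed=rng_seed)


# --------------------------------------------- geocoder benchmark utilities

_REVERSE_ABBREV = {"chemin": "ch.", "avenue": "av.", "boulevard": "bd.",
                   "rue": "r.", "route": "rte", "place": "pl."}


def generate_registry(n_entries: int = 5000, n_postal: int = 12,
                      rng_seed: int = 0) -> pd.DataFrame:
    """Standalone synthetic building registry (for geocoder benchmarks).

    ~10 buildings per street, globally unique street names, coordinates
    uniform on a 10 km square.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    street_idx = 0
    while len(rows) < n_entries:
        name = _street_name(street_idx)
        postal = str(1200 + street_idx % n_postal)
        n_b = int(rng.integers(5, 16))
        for b in range(n_b):
            xy = rng.uniform(0, 10000, 2)
            rows.append((name, str(b + 1), postal, xy[0], xy[1]))
        street_idx += 1
    return pd.DataFrame(rows[:n_entries],
                        columns=["street_name", "street_number",
                                 "postal_code", "x", "y"])


def perturb_address(street_name: str, street_number: str,
                    rng: np.random.Generator) -> str:
    """Re-abbreviate the street type and delete one letter.

    Produces the kind of messy-but-matchable address the geocoder is meant
    to resolve: "chemin des roses 5" → "ch. des rses 5".
    """
    tokens = street_name.split()
    if tokens[0] in _REVERSE_ABBREV:
        tokens[0] = _REVERSE_ABBREV[tokens[0]]
    name = " ".join(tokens)
    letters = [i for i, c in enumerate(name) if c.isalpha() and i > len(tokens[0])]
    if letters:
        i = int(rng.choice(letters))
        name = name[:i] + name[i + 1:]
    return f"{name} {street_number}"
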