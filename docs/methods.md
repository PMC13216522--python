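# Methods

This note documents the statistical procedures implemented in
`screenscape`, the choices made where the methods literature leaves
latitude, what the synthetic benchmark does and does not establish, and the
package's known limitations.

## Rate panel and smoothing

Invitations are pooled into biennial periods labelled by the even year (an
odd year maps to the following even year), matching the two-year invitation
cycle. Points are assigned to the containing neighborhood polygon; points
outside every polygon go to the nearest polygon by boundary distance, and
exact boundary ties are resolved uniformly at random under a fixed seed so
repeated runs agree. Cells with zero invitations are *missing*, never
zero-rate.

The raw rate rᵢ = 100·oᵢ/nᵢ from a small denominator is unstable, so rates
are shrunk with spatial empirical Bayes smoothing over the window
Jᵢ = {i} ∪ {8 nearest neighbours by centroid distance}, rebuilt per period
among the units observed in that period:

    mᵢ = Σ_{j∈J} oⱼ / Σ_{j∈J} nⱼ
    vᵢ = Σ_{j∈J} nⱼ (rⱼ − mᵢ)² / Σ_{j∈J} nⱼ − mᵢ / (Σ_{j∈J} nⱼ / |Jᵢ|)
    wᵢ = vᵢ / (vᵢ + mᵢ/nᵢ),  θᵢ = mᵢ + wᵢ (rᵢ − mᵢ)

on the proportion scale, reported ×100. The method-of-moments variance vᵢ
is floored at zero (full shrinkage to the local mean), the standard
convention; θᵢ therefore always lies between rᵢ and mᵢ, and larger nᵢ
shrink less. The exact moment formulas above are pinned and unit-tested
against their own closed form so results do not drift with library
versions. Note the Poisson-style mᵢ/nᵢ sampling-variance term: when
between-unit variance is small relative to it, smoothing collapses rates
onto local means — a property with consequences for inference discussed
under "benchmark design" below.

File writers keep 6 decimals so stage chaining through CSV is lossless;
display output rounds to one decimal.

## Getis-Ord Gi\*

With binary, self-included KNN weights (every unit has exactly k
neighbours; k = 16 retained for cross-sectional reporting, k = 8 available),

    zᵢ = [Σⱼ wᵢⱼxⱼ − x̄ Wᵢ] / (S · sqrt[(n Σⱼ wᵢⱼ² − Wᵢ²)/(n−1)])

where x̄ and S are the global mean and population standard deviation
including unit i. KNN ties are broken by unit order, making weights fully
deterministic. Inference is by conditional permutation: the focal value is
held fixed and its window is refilled with k draws (without replacement)
from the other n−1 values; one shared permutation-index table serves all
units, the standard conditional-randomisation shortcut. The pseudo-p is
(#{|z_perm| ≥ |z_obs|} + 1)/(M + 1) — a two-sided exceedance count with the
hot/cold label taken from the sign of the observed z — so under an
exchangeable null the rejection rate at p < 0.05 is ≈ 0.045–0.05 regardless
of the direction split, and p is never zero. Units missing a rate in a
period are dropped and weights rebuilt, so every retained unit keeps k
neighbours.

## Emerging hot spot analysis

The space-time cube holds one smoothed rate per (neighborhood, period);
missing bins are masked, never imputed. Each bin is scored with the same
Gi\* formula over the window {i} ∪ spatial-KNN(i) crossed with time lags
{−1, 0, +1}, with masked bins excluded and Wᵢ renormalised per bin; the
global moments are taken over all observed bins, and a two-sided normal
p-value accompanies each z. Benjamini–Hochberg FDR at α = 0.05 is applied
jointly across all bins; rejected bins are "hot" or "cold" by the sign of
z.

The cube's spatial neighbourhood defaults to **k = 8** (configurable). The
cross-sectional analysis retains k = 16, but the cube statistic pools 3
temporal lags, so its window already spans ~27 bins at k = 8; with k = 16
the ~51-bin windows of adjacent locations overlap almost completely, and a
single chance exceedance propagates across ~15 neighbouring locations.
Benchmark runs showed that this turns isolated noise into spurious
multi-neighborhood "emerging" patterns; k = 8 halves the footprint while
leaving genuine cores detected. This is a deliberate design choice for the
cube stage, not a claim about the cross-sectional statistic.

Per location, the Mann-Kendall test is applied to the series of bin
z-scores over observed periods — the trend of cluster *intensity*, not of
the raw rate:

    S = Σ_{i<j} sgn(xⱼ − xᵢ)
    Var(S) = [n(n−1)(2n+5) − Σ_ties t(t−1)(2t+5)] / 18
    z = (S∓1)/√Var(S)  (continuity-corrected, 0 when S = 0)

with two-sided normal p and α_trend = 0.05. Series with fewer than 4
observed values get direction "none"; locations observed in fewer than 2
periods are labelled no-pattern.

Classification uses the 17-label rule table over the post-FDR hot/cold
indicator series, evaluated in fixed precedence order for the hot family —
new (hot only in the final period), consecutive (uninterrupted final run of
≥2, no earlier hot, <90% of periods), intensifying / persistent /
diminishing (hot in ≥90% of periods, by trend direction), sporadic (hot
final, <90%, no cold periods), oscillating (hot final, ≥1 earlier cold,
<90%), historical (not hot in the final period but hot in ≥**50%** of
periods — the threshold deliberately relaxed from the conventional 90%) —
then the mirrored cold family only if no hot label fired, with the trend
orientation flipped (an intensifying cold spot is one whose z trends
downward); anything left is no-pattern. The classifier is verified
exhaustively (every indicator string of length 9 × every trend state)
against an independently coded reading of the rule table.

## Accessibility

Query points and centers snap to their nearest street-network node (ties to
the smallest node id; the snap leg is ignored by default, configurable).
The score is Σ over centers active in the period with network shortest-path
distance d ≤ 5000 m of (1 − d/5000); unreachable centers count zero. The
raw decayed sum is reported without normalisation. A center contributes
from its opening period through its closing period inclusive.

## Determinants model

Features per neighborhood: deprivation index, accessibility score,
five-year age shares of invited women in the final period, and centroid
coordinates (to absorb residual geography). Outcome: final-period smoothed
rate (a raw-rate sensitivity flag exists because smoothing itself induces
spatial structure that the coordinate features can pick up). The 80/20
split is seeded and recorded. Hyperparameters (max_depth 2–8,
learning_rate 0.01–0.3 log, min_child_weight 1–16 log, subsample 0.5–1,
colsample_bytree 0.5–1, reg_lambda 0.01–10 log; 500 rounds, early stopping
at 25) are tuned by sequential model-based optimisation — a Matern-5/2
Gaussian-process surrogate with fixed length scale and
expected-improvement acquisition over 256 random candidates, 8 initial
random evaluations — minimising mean 5-fold CV RMSE on the training split.
The final model trains with early stopping on a 10% validation slice of
the training data and is evaluated once on the untouched test split.
Single-thread histogram trees make the whole procedure bit-reproducible
under a fixed seed.

Attributions use xgboost's exact TreeSHAP (`pred_contribs` /
`pred_interactions`): per-row contributions summing to the prediction,
mean |contribution| as the importance ranking, and mean |interaction| as
the pairwise summary. Because the trees are single precision, row-wise
local accuracy holds to ~1e-4 on a percent-scale outcome, and tests assert
it at that tolerance.

## The synthetic canton

The generator emulates the *data layout* of a dense canton's screening
program: Voronoi neighborhoods from uniform seeds clipped to a square
(side 600·√n metres, so ~0.36 km² per neighborhood), deprivation as
Gaussian-kernel-smoothed white noise min-max scaled to [0, 1]
(autocorrelation scale 1500 m), population concentrated toward an urban
core, a perturbed-grid street network with Euclidean edge lengths, ~10
screening centers Gaussian-scattered around the core (a third opening or
closing mid-study), a building registry with globally unique street names,
and women fixed at one address with study-start ages uniform on 48–74 so
the cohort turns over. Participation is Bernoulli with

    logit p = intercept + β_dep·deprivation + β_acc·access + u_{it} + shift_{it}

where u_{it} is *transient* neighborhood-by-period noise (sd 0.9 log-odds
by default) and shift_{it} plants the cluster trajectories. All randomness
derives from one seed through salted `SeedSequence` streams.

**Benchmark design.** Two interacting artifacts shaped the defaults, and
they are worth stating because they generalise to real data:

* If between-unit variance is pure binomial, the SEBS variance floor makes
  wᵢ = 0 everywhere and every smoothed rate collapses onto its local-window
  mean; the cube then carries strong *manufactured* spatial correlation,
  bin z-scores are over-dispersed by a factor ~2, and once any genuine
  signal lowers the adaptive BH bar the background floods with spurious
  categories. Realistic extra-binomial noise (here 0.9 log-odds per cell,
  with ~115 invitations per cell) keeps wᵢ ≈ 0.9 and the null z near
  standard.
* Heterogeneity that is *constant in time* is indistinguishable from many
  tiny planted persistent spots — Gi\* correctly flags persistently
  elevated local means, whatever generated them. For the planted truth to
  be well-defined, background noise must therefore be transient; the
  generator draws u independently per cell by design.

The default demo canton (400 neighborhoods, 9 periods, seed-driven) plants
a persistent and an intensifying hot core of 13 neighborhoods at +1.8
log-odds (ramping 0.9→2.7 for the intensifying core) with mild covariate
effects (+0.15 deprivation, −0.05 access); across 32 generator seeds the
emerging-hot-spot stage recovers ≥85% of planted core neighborhoods into
hot-family categories while flagging ≤8% of background. All trajectory
families (diminishing, new, sporadic, historical, cold mirrors) are
available through `PatternPlan` and exercised by `full_pattern_spec`. The
determinants benchmark uses a separate single-period spec (2000
neighborhoods, ~150k women, dominant effects +1.5/−0.4, overdispersion
0.1) because covariate-effect recovery needs the covariates, not the
planted clusters, to dominate the outcome surface.

What passing the synthetic benchmark does **not** show about real data:
real participation has persistent neighborhood effects, migration,
opportunistic screening outside the program, and deprivation gradients far
stronger than the demo defaults — on such data the pipeline will (rightly)
categorise much more of the map, and the no-pattern share is not
comparable. The benchmark validates the machinery, not the prevalence of
patterns.

## Numerical and degenerate-input conventions

Constant surfaces raise a degenerate-surface signal (cross-section) or
yield all-"neither" bins (cube). Zero-invitation cells are missing, not
zero. Negative SEBS variance floors at zero; wᵢ is defined 0 when both vᵢ
and mᵢ/nᵢ vanish. KNN and snapping ties break toward smaller indices;
boundary-point neighborhood ties break by seeded uniform choice.
Permutation tables are shared across focal units. Geocoding ties prefer
the query's postal code, then the lexicographically smallest registry key;
manual review near the threshold is replaced by an exported similarity
band (0.75–0.85).

## Problem sizes

Defaults were chosen so the full validation chain runs in about a minute
on a single CPU: cube statistics on 3600 bins, 199-permutation calibration
over 200 replicate surfaces (the package default for reported analyses
remains 9999 permutations), a 2000-row model fit with 12 optimisation
evaluations, and a 5000-entry geocoder benchmark.

## Known limitations

* The EHSA analytic bin p-values inherit whatever correlation the smoothed
  values carry; FDR across bins does not model window overlap. Interpret
  isolated consecutive/new/sporadic categories cautiously.
* Accessibility ignores the Euclidean snap leg and does not model capacity
  or competition (no two-step floating catchment).
* The geocoder ships a deliberately small, extensible abbreviation
  dictionary; coverage of real address idiosyncrasies depends on extending
  it.
* Age composition enters the model but not the rate construction (no
  age-standardised rates).
* The determinants model is predictive, not causal; coordinate features
  absorb — and can mask — smooth spatial confounding.
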