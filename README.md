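# screenscape

Spatiotemporal analysis of participation in organized cancer-screening
programs, at the neighborhood scale.

Organized breast-cancer screening mails biennial invitations to every woman
aged 50–74; whether she attends varies strongly across a city, and the
geography of that variation — where participation clusters low, where it is
eroding, where it is improving — is what program coordinators need for
targeted outreach. `screenscape` packages the full analysis chain used for
that question as a tested Python library:

1. **Offline fuzzy geocoding** of address strings against a building
   registry (normalization + Ratcliff–Obershelp similarity, quick pass
   within the postal code, slow pass canton-wide, street-centroid fallback,
   0.80 acceptance threshold). No address ever leaves the machine.
2. **Rate construction**: invitations pooled into biennial periods labelled
   by the even year, assigned to the nearest inhabited neighborhood, and
   aggregated to participation rates (participants/invitations × 100), then
   stabilised with **spatial empirical Bayes smoothing** (SEBS, 8 nearest
   neighbours): θᵢ = mᵢ + wᵢ(rᵢ − mᵢ) with wᵢ = vᵢ/(vᵢ + mᵢ/nᵢ), where mᵢ
   and vᵢ are the local reference rate and local variance.
3. **Hot spot detection** with the Getis-Ord Gi\* statistic on binary
   k-nearest-neighbour weights (k = 16, self included), pseudo-p-values
   from conditional Monte-Carlo permutation (9999 by default), graduated
   significance tiers (p < 0.001/0.01/0.05/0.1).
4. **Emerging hot spot analysis**: a space-time cube of smoothed rates,
   Gi\* per bin over a spatial-KNN × ±1-period window, Benjamini–Hochberg
   FDR across all bins, a Mann-Kendall intensity trend per location, and a
   17-category rule table (new, consecutive, intensifying, persistent,
   diminishing, sporadic, oscillating, historical — hot and cold — or no
   pattern), with the Historical threshold at 50% of time steps.
5. **Accessibility**: density of active screening centers within 5000 m of
   street-network distance, linearly decayed (1 − d/5000), per period.
6. **Determinants**: XGBoost regression of final-period smoothed rates on
   deprivation, accessibility, age composition and coordinates — 80/20
   split, Bayesian hyperparameter optimisation over 5-fold CV RMSE, early
   stopping — interpreted with exact TreeSHAP attributions.

Because real invitation data are confidential, the package ships a
first-class **synthetic canton generator**: Voronoi neighborhoods, a
spatially autocorrelated deprivation index, an urban-core center layout, a
street network, a building registry, and invitation streams whose
participation probabilities contain *planted* spatial clusters following
prescribed temporal trajectories. Every downstream stage can therefore be
validated against known ground truth.

## Worked example

```python
import screenscape as ss

spec = ss.default_spec(rng_seed=1)           # 400 neighborhoods, 9 periods
canton = ss.simulate(spec)                   # planted persistent + intensifying cores
panel, _ = ss.build_panel(canton.invitations, canton.neighborhoods,
                          spec.period_labels, rng_seed=0)
result = ss.ehsa(panel, canton.neighborhoods[["neighborhood_id", "x", "y"]])
print(result["locations"]["category"].value_counts())
```

prints

```
no_pattern          367
persistent_hot       10
consecutive_hot       9
intensifying_hot      6
sporadic_hot          3
historical_hot        2
consecutive_cold      1
new_hot               1
new_cold              1
```

The 13 neighborhoods planted as a persistent hot core come out 92% in
hot-family categories (10 persistent, 2 consecutive), the intensifying core
85%, and only ~3% of background neighborhoods receive any category — the
pipeline recovers the planted structure without inventing patterns
elsewhere. On the dominant-effects determinants benchmark (2000
neighborhoods) the tuned model reaches test R² = 0.93 with RMSE = 2.1
percentage points, and the SHAP ranking puts deprivation (mean |SHAP| 4.0,
positive direction) and accessibility (2.1, negative direction) above every
age-share predictor.

The `examples/` directory holds one short narrative script per capability
(simulation, geocoding, smoothing, hot spots, emerging patterns,
accessibility, determinants, full pipeline); each prints the numbers it
computes and says what they mean. A thin CLI mirrors the library:

```bash
screenscape run-all --config config.yaml
screenscape geocode --addresses a.csv --registry r.csv --out g.csv
```

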