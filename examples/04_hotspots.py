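"""Cross-sectional Getis-Ord Gi* hot/cold spot detection.

Each neighborhood's smoothed rate is compared, together with its k=16
nearest neighbours, against the canton-wide mean; significance comes from
conditional Monte-Carlo permutation and is reported in graduated tiers.
"""

import screenscape as ss
from screenscape.hotspots import hotspot_analysis

spec = ss.default_spec(rng_seed=1)   # 400 neighborhoods, 9 periods
canton = ss.simulate(spec)
panel, _ = ss.build_panel(canton.invitations, canton.neighborhoods,
                          spec.period_labels, rng_seed=0)
cent = canton.neighborhoods[["neighborhood_id", "x", "y"]]

gi = hotspot_analysis(panel[panel["period"] == 2020], cent,
                      k=16, n_perm=999, rng_seed=1)
print("2020 cross-section, graduated significance classes:")
print(gi["class"].value_counts().to_string())

truth = canton.truth.set_index("neighborhood_id")["trajectory"]
planted = truth[truth != "none"].index
hits = gi.set_index("neighborhood_id").loc[planted, "class"]
print(f"\nplanted hot-core neighborhoods flagged hot: "
      f"{hits.str.startswith('hot').mean() * 100:.0f}%")
print("z > 0 with small pseudo-p marks clusters of high participation; "
      "the tiers mirror map-intensity grading.")
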