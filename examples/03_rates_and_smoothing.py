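"""Biennial rate panel with spatial empirical Bayes smoothing.

Invitations are pooled into two-year periods labelled by the even year and
aggregated per neighborhood; raw rates from small denominators are then
shrunk toward the local 8-neighbour reference rate.  The smaller the
denominator, the stronger the shrinkage.
"""

import screenscape as ss

spec = ss.default_spec(rng_seed=1, n_neighborhoods=100, n_women=8000)
canton = ss.simulate(spec)
panel, stats = ss.build_panel(canton.invitations, canton.neighborhoods,
                              spec.period_labels, k=8, rng_seed=0)
print(f"panel: {len(panel)} neighborhood-period cells "
      f"({stats['rows_used']} invitations used)")

final = panel[panel["period"] == 2020].copy()
final["shrinkage_pp"] = (final["sebs_rate"] - final["raw_rate"]).abs()
small = final[final["n"] <= final["n"].quantile(0.2)]
large = final[final["n"] >= final["n"].quantile(0.8)]
print(f"\nmean |smoothed - raw| in 2020:")
print(f"  smallest-denominator quintile (n<= {int(final['n'].quantile(0.2))}): "
      f"{small['shrinkage_pp'].mean():.2f} pp")
print(f"  largest-denominator quintile  (n>= {int(final['n'].quantile(0.8))}): "
      f"{large['shrinkage_pp'].mean():.2f} pp")
print("\nsmall cells move the most: empirical Bayes stabilises exactly the "
      "rates that binomial noise hits hardest.")
print(final[["neighborhood_id", "n", "o", "raw_rate", "sebs_rate"]]
      .head(5).round(1).to_string(index=False))
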