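"""Offline fuzzy geocoding against a building registry.

Addresses are normalized (abbreviations expanded, diacritics stripped, the
street number extracted) and matched with the Ratcliff-Obershelp similarity
ratio: a quick pass within the postal code, then a canton-wide slow pass.
Matched streets without a matching number fall back to the street centroid.
"""

import numpy as np
import pandas as pd

from screenscape.geocoding import Registry, geocode, geocode_table, review_band
from screenscape.synthetic import generate_registry, perturb_address

registry_df = generate_registry(n_entries=2000, rng_seed=0)
registry = Registry(registry_df)

for raw, postal in [("Chemin des Monver 3", "1200"),
                    ("ch. des monver 3", "1200"),     # abbreviated
                    ("chemin des monver", "1200"),    # no number
                    ("qqq zzz 1", "1200")]:           # unmatchable
    r = geocode(raw, registry, postal_code=postal)
    sim = "-" if r.similarity is None else f"{r.similarity:.2f}"
    print(f"{raw!r:32s} -> method={r.method:15s} similarity={sim}")

# round trip: perturb registry addresses (re-abbreviate + one deletion)
rng = np.random.default_rng(0)
sample = registry_df.sample(300, random_state=1)
addresses = pd.DataFrame({
    "address": [perturb_address(s, n, rng)
                for s, n in zip(sample["street_name"], sample["street_number"])],
    "postal_code": sample["postal_code"].to_numpy()})
out = geocode_table(addresses, registry)
hit = ((out["x"].to_numpy() == sample["x"].to_numpy())
       & (out["y"].to_numpy() == sample["y"].to_numpy()))
print(f"\nround trip: {100 * hit.mean():.1f}% of perturbed addresses "
      "resolve to the true building")
print(f"review band (similarity 0.75-0.85): {len(review_band(out))} addresses "
      "flagged for manual audit")
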