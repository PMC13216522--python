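"""Generate a synthetic canton and inspect its planted structure.

The generator emulates the inputs of an organized screening program:
neighborhood polygons, a 0-1 deprivation surface, screening centers, a
street network, a building registry and a biennial invitation stream, with
two planted hot cores whose locations are recorded as ground truth.
"""

import screenscape as ss

spec = ss.default_spec(rng_seed=1, n_neighborhoods=100, n_women=8000)
canton = ss.simulate(spec)

print(f"neighborhoods: {len(canton.neighborhoods)}")
print(f"women:         {len(canton.women)}")
print(f"invitations:   {len(canton.invitations)}  "
      f"(periods {spec.period_labels[0]}-{spec.period_labels[-1]})")
print(f"registry:      {len(canton.registry)} buildings")
print(f"overall participation: "
      f"{100 * canton.invitations['participated'].mean():.1f}%")
print("\nplanted truth (neighborhood counts):")
print(canton.truth["trajectory"].value_counts().to_string())
# The participation rate inside a planted hot core sits well above the
# background: that contrast is what the downstream stages must recover.
truth = canton.truth.set_index("neighborhood_id")["trajectory"]
inv = canton.invitations.assign(
    traj=truth.loc[canton.invitations["neighborhood_id"]].to_numpy())
print("\nraw participation by planted trajectory:")
print((100 * inv.groupby("traj")["participated"].mean()).round(1).to_string())
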