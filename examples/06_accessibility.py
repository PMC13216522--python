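"""Street-network accessibility with linear distance decay.

A center at network distance d contributes (1 - d/5000) to the score within
a 5000-m radius, zero beyond.  Openings and closings make the score vary by
biennial period.
"""

import numpy as np
import pandas as pd

import screenscape as ss

# a 7-node line network, 1000 m between consecutive nodes
nodes = pd.DataFrame({"node_id": np.arange(7), "x": np.arange(7) * 1000.0,
                      "y": 0.0})
edges = pd.DataFrame({"u": np.arange(6), "v": np.arange(1, 7),
                      "length": 1000.0})
net = ss.StreetNetwork(nodes=nodes, edges=edges)
centers = pd.DataFrame({
    "center_id": [0, 1], "x": [1000.0, 4000.0], "y": [0.0, 0.0],
    "first_active_period": [2004, 2012], "last_active_period": [2020, 2020]})

score = ss.access_score((0.0, 0.0), centers, net, radius=5000.0)
print(f"both centers active: score at x=0 is {score:.2f} "
      "(= (1-1000/5000) + (1-4000/5000) = 0.8 + 0.2)")

pts = pd.DataFrame({"neighborhood_id": [0], "x": [0.0], "y": [0.0]})
panel = ss.access_panel(pts, centers, net, range(2004, 2021, 2))
print("\nper-period score at x=0 (second center opens in 2012):")
print(panel.set_index("period")["access"].round(2).to_string())
print("\nthe 2012 step up is the opening of the second center; scores are "
      "dimensionless decayed center counts.")
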