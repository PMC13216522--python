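import numpy as np
import pytest

import screenscape as ss
from screenscape.synthetic import CantonSpec, PatternPlan


@pytest.fixture(scope="session")
def small_spec():
    """A 60-neighborhood canton with one planted hot core: fast plumbing."""
    return CantonSpec(
        n_neighborhoods=60, n_women=3000, rng_seed=7,
        planted_patterns=(PatternPlan("persistent_hot", 1.8, size=8),))


@pytest.fixture(scope="session")
def small_canton(small_spec):
    return ss.simulate(small_spec)


@pytest.fixture(scope="session")
def small_panel(small_canton, small_spec):
    panel, _ = ss.build_panel(small_canton.invitations,
                              small_canton.neighborhoods,
                              small_spec.period_labels, rng_seed=0)
    return panel


@pytest.fixture(scope="session")
def small_centroids(small_canton):
    return small_canton.neighborhoods[["neighborhood_id", "x", "y"]]
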