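import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from habitatshift.change import ClassScheme
from habitatshift.synthetic import LandscapeSpec, gen_landscape_pair

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme4():
    return ClassScheme.from_labels("synthetic4", ["shrub", "crop", "urban", "water"])


@pytest.fixture(scope="session")
def landscape_pair(scheme4):
    """200x200 two-date landscape with off-diagonal transitions + zones."""
    P = np.array([
        [0.90, 0.05, 0.04, 0.01],
        [0.02, 0.95, 0.03, 0.00],
        [0.00, 0.00, 1.00, 0.00],
        [0.05, 0.00, 0.00, 0.95],
    ])
    spec = LandscapeSpec(scheme4, shape=(200, 200),
                         mixing=(0.5, 0.25, 0.15, 0.1),
                         transition=tuple(map(tuple, P)),
                         cell_area=0.0009, n_zones=4,
                         start_year=2000, end_year=2020)
    return gen_landscape_pair(spec, seed=42)


def brute_force_transitions(g0, g1):
    """Independent oracle: per-cell pair counting with a python dict."""
    counts = {}
    nodata = g0.scheme.nodata_code
    for a, b in zip(g0.values.ravel(), g1.values.ravel()):
        if a == nodata or b == nodata:
            continue
        counts[(int(a), int(b))] = counts.get((int(a), int(b)), 0) + 1
    ids = g0.scheme.class_ids
    out = pd.DataFrame(0.0, index=ids, columns=ids)
    for (a, b), c in counts.items():
        out.loc[a, b] = c * g0.cell_area
    return out
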