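import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phenocrop as pc

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: Confusion matrix of the reference accuracy table (rows: map estimates,
#: columns: reference data; class order rice, wheat, maize, others).
REFERENCE_MATRIX = np.array(
    [
        [5929, 45, 56, 357],
        [78, 2220, 139, 220],
        [205, 90, 4216, 151],
        [366, 85, 212, 4010],
    ]
)
REFERENCE_CLASSES = ("rice", "wheat", "maize", "others")


@pytest.fixture(scope="session")
def reference_matrix():
    return REFERENCE_MATRIX.copy()


@pytest.fixture(scope="session")
def clean_pixels():
    """One noise-free pure pixel per pattern code, with smoothed indices."""
    from phenocrop.preprocess import smooth_indices

    out = {}
    for code in pc.VALID_CODES:
        series = pc.simulate_pixel(code, purity=1.0, seed=0)
        out[code] = (series, smooth_indices(series))
    return out


@pytest.fixture(scope="session")
def small_scene():
    """4x4 noise-free pure scene cycling through some codes."""
    pm = pc.demo_pattern_map(4, 4)
    cfg = pc.SceneConfig(4, 4, pm, np.ones((4, 4)), 0.0, 0.0, seed=7)
    return pc.simulate_scene(cfg)
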