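import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# fit-diagnostic warnings are expected in degenerate-input tests
logging.getLogger("mqpi").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def linear_track():
    """Noiseless linear-growth track: m(t) = 200 + 4 t pg over 48 h."""
    from mqpi.datatypes import CellTrack

    t = np.arange(0.0, 48.0 + 1e-9, 1.0 / 3.0)
    return CellTrack(track_id=0, frames=np.arange(t.size), times_h=t,
                     masses_pg=200.0 + 4.0 * t)
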