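import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from evconv import Event, EventStream


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_stream(rng, n, x_max=32, y_max=32, t_max=10**6, with_k=False):
    ts = np.sort(rng.integers(0, t_max, size=n))
    events = [
        Event(
            int(t),
            int(rng.integers(0, x_max)),
            int(rng.integers(0, y_max)),
            int(rng.choice([-1, 1])),
            int(rng.integers(0, 4)) if with_k and rng.random() < 0.5 else None,
        )
        for t in ts
    ]
    return EventStream(events, (x_max, y_max))


@pytest.fixture
def make_random_stream(rng):
    return lambda n, **kw: random_stream(rng, n, **kw)
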