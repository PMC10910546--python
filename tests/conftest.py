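import numpy as np
import pytest

from tiltpipe.broker import InMemoryBroker
from tiltpipe.synthetic import build_schedule, make_phantom, replay


class FakeClock:
    """Settable clock for broker deadline tests."""

    def __init__(self, t: float = 0.0) -> None:
        self.t = t

    def __call__(self) -> float:
        return self.t

    def advance(self, dt: float) -> None:
        self.t += dt


@pytest.fixture
def clock():
    return FakeClock()


@pytest.fixture
def broker(clock):
    return InMemoryBroker(["motioncorr", "ctffind"], delivery_limit=3, clock=clock)


@pytest.fixture(scope="session")
def phantom():
    """One reproducible sphere phantom shared by the numeric tests."""
    return make_phantom(dims=(64, 64, 64), n_spheres=5, seed=7)


@pytest.fixture(scope="session")
def small_session(tmp_path_factory):
    """A replayed 2-series x 5-tilt acquisition (read-only for tests)."""
    root = tmp_path_factory.mktemp("detector")
    schedule = build_schedule("sequential", n_series=2, n_tilts=5)
    manifest = replay(schedule, root, seed=21, time_scale=0.0)
    return root, manifest
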