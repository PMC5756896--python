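import numpy as np
import pytest

from songspace import SongTimeline


def random_timeline(rng, individual="X", window=(0.0, 60.0), max_songs=8):
    """A valid random timeline: sorted disjoint intervals inside the window."""
    t0, t1 = window
    n = int(rng.integers(0, max_songs + 1))
    pts = np.sort(rng.uniform(t0, t1, 2 * n))
    intervals = [(pts[2 * i], pts[2 * i + 1]) for i in range(n)
                 if pts[2 * i + 1] - pts[2 * i] > 1e-6]
    return SongTimeline(individual, tuple(intervals), window)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_timeline(rng):
    def _make(individual="X", window=(0.0, 60.0), max_songs=8):
        return random_timeline(rng, individual, window, max_songs)
    return _make
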