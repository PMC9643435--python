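import numpy as np
import pytest

from lymphodyn.tracks import Track


def make_track(points, track_id="t0", pixel_size=0.4, frame_interval=20.0, **kw):
    """Track from a list of (t, x, y) triples (pixel units)."""
    arr = np.asarray(points, dtype=float)
    return Track(
        track_id=track_id,
        t=arr[:, 0].astype(int),
        x=arr[:, 1],
        y=arr[:, 2],
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        **kw,
    )


def random_walk_track(rng, n=30, step_scale=2.0, track_id="rw", **kw):
    """Uncorrelated random walk: uniform heading, exponential step length."""
    headings = rng.uniform(-np.pi, np.pi, n - 1)
    steps = rng.exponential(step_scale, n - 1)
    dx = steps * np.cos(headings)
    dy = steps * np.sin(headings)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    return Track(track_id=track_id, t=np.arange(n), x=x, y=y, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def session_rng():
    return np.random.default_rng(7)
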