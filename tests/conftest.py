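import numpy as np
import pytest

from ivtrack.model import AcquisitionParams, Track, TrackSet


def make_track(points, tid="t1", fi=1.0, cell_class="", condition=""):
    """Build a Track from (t, x, y[, z]) tuples."""
    pts = [tuple(p) for p in points]
    has_z = len(pts[0]) == 4
    return Track(
        track_id=tid,
        t=np.array([p[0] for p in pts], float),
        x=np.array([p[1] for p in pts], float),
        y=np.array([p[2] for p in pts], float),
        z=np.array([p[3] for p in pts], float) if has_z else None,
        cell_class=cell_class,
        condition=condition,
        frame_interval=fi,
    )


def make_set(tracks, condition="", fi=1.0):
    return TrackSet(tracks=list(tracks), condition=condition,
                    acquisition=AcquisitionParams(frame_interval=fi))


@pytest.fixture
def straight_track():
    """Constant-velocity 1 µm/min track along x."""
    return make_track([(t, float(t), 0.0) for t in range(11)])


@pytest.fixture
def stationary_track():
    return make_track([(t, 2.0, -3.0) for t in range(11)])


def random_track(rng, n_points=None, tid="r", fi=1.0, step_sigma=2.0):
    n = n_points or rng.integers(5, 51)
    steps = rng.normal(0, step_sigma, size=(n - 1, 2))
    pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return make_track([(i * fi, pos[i, 0], pos[i, 1]) for i in range(n)], tid=tid, fi=fi)
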