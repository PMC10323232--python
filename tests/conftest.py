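import numpy as np
import pytest

from epievents.io import RunConfig
from epievents.scaling import AnnotationSet, EventClass, EventPoint, Movie
from epievents.synth import SynthConfig, generate_movie


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_movie(rng):
    """A 20-frame 64×64 random movie at the reference calibration."""
    frames = rng.random((20, 64, 64)).astype(np.float32) * 100
    return Movie(frames, pixel_size=0.275, frame_interval=5.0)


@pytest.fixture
def random_events(rng):
    events = []
    seen = set()
    classes = list(EventClass)
    while len(events) < 100:
        e = EventPoint(
            x=int(rng.integers(0, 500)),
            y=int(rng.integers(0, 500)),
            t=int(rng.integers(0, 200)),
            event_class=classes[int(rng.integers(0, 4))],
            probability=float(np.round(rng.random(), 3)),
        )
        if e.key() not in seen:
            seen.add(e.key())
            events.append(e)
    return AnnotationSet(events, (0.275, 5.0))


@pytest.fixture(scope="session")
def tiny_tissue():
    """A small synthetic tissue with a few planted events (session-cached)."""
    cfg = SynthConfig(size=(128, 128), n_frames=30, n_extrusions=2,
                      n_divisions=1, margin=25, seed=21)
    movie, annotations, geometry = generate_movie(cfg)
    return movie, annotations, geometry


@pytest.fixture
def default_config():
    return RunConfig()
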