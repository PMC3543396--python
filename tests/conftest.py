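import numpy as np
import pytest

from motiongate import FrameStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb_stack(rng):
    """Seeded 8-frame 32x32 RGB stack of uniform noise."""
    frames = rng.integers(0, 256, size=(8, 32, 32, 3), dtype=np.uint8)
    return FrameStack(frames=frames)


@pytest.fixture
def random_gray_stack(rng):
    frames = rng.integers(0, 256, size=(6, 24, 24, 1), dtype=np.uint8)
    return FrameStack(frames=frames, channel_names=("gray",))


def constant_stack(value: int, T: int = 10, H: int = 16, W: int = 16, C: int = 1):
    frames = np.full((T, H, W, C), value, dtype=np.uint8)
    names = ("red", "green", "blue") if C == 3 else ("gray",)
    return FrameStack(frames=frames, channel_names=names)


@pytest.fixture
def scores_to_series():
    """Build a ScoreSeries from a plain list of scores."""
    from motiongate import ReferencePolicy, ScoreSeries

    def build(scores, origin=None):
        scores = np.asarray(scores, dtype=float)
        if origin is None:
            origin = np.arange(len(scores))
        return ScoreSeries(
            scores=scores,
            origin_indices=np.asarray(origin),
            policy=ReferencePolicy(mode="single", single_index=0),
            channel="gray",
        )

    return build
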