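import numpy as np
import pytest

from dxblink.preprocess import PixelTrace
from dxblink.simulate import RingGeometry, SimulationConfig, simulate_movie
from dxblink.stack_io import FrameStack


@pytest.fixture(scope="session")
def small_ring() -> RingGeometry:
    """Ring small enough for fast end-to-end runs."""
    return RingGeometry(shape=(72, 72), center=(36.0, 36.0), radius=30.0, halfwidth=1.5)


@pytest.fixture(scope="session")
def small_movie(small_ring):
    """48-spot, 400-frame telegraph movie with its ground truth."""
    cfg = SimulationConfig(n_spots=48, k_on=0.3, k_off=0.3, n_frames=400, seed=12345)
    stack, truth = simulate_movie(cfg, small_ring)
    return stack, truth, cfg


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def make_trace(values, dt: float = 0.05) -> PixelTrace:
    return PixelTrace(np.asarray(values, dtype=float), row=0, col=0, frame_interval=dt)


@pytest.fixture()
def tiny_stack() -> FrameStack:
    counts = np.arange(2 * 6 * 6, dtype=np.uint16).reshape(2, 6, 6)
    return FrameStack(counts, frame_interval=0.05, exposure=0.042)
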