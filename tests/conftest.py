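import numpy as np
import pytest

from fura2track import (
    PhantomSpec,
    SegmentationParams,
    gen_phantom,
    random_dropout_schedule,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """Tiny clean phantom: 6 cells, 12 frames, no motion, no dropout."""
    spec = PhantomSpec(
        shape=(128, 128),
        n_frames=12,
        n_cells=6,
        motion_sd=0.0,
        noise_sd=0.0,
        area_sd=0.0,
        peak_frame=6,
        seed=3,
    )
    return gen_phantom(spec)


@pytest.fixture(scope="session")
def benchmark_phantom():
    """The 50-frame, 30-cell slow-motion phantom with transient dropouts."""
    dropout = random_dropout_schedule(30, 50, fraction=0.10, block_len=2, seed=7)
    spec = PhantomSpec(
        shape=(256, 256),
        n_frames=50,
        n_cells=30,
        motion_sd=0.5,
        dropout=dropout,
        seed=7,
    )
    return gen_phantom(spec)


@pytest.fixture()
def default_params():
    return SegmentationParams(w=20)
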