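import numpy as np
import pytest

from echovid.mae_core import EncoderConfig
from echovid.tokenization import CubeGridSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_grid():
    return CubeGridSpec(T=8, tau=2, H=32, h=8, W=32, w=8, d_model=64)


@pytest.fixture
def tiny_encoder_cfg():
    return EncoderConfig(depth=2, d_model=64, heads=4, mlp_ratio=2.0,
                         decoder_depth=1, decoder_width=32, decoder_heads=2)


@pytest.fixture
def micro_grid():
    # 2x2x2 grid of 2x4x4 cubes on an 8-frame 8x8 clip
    return CubeGridSpec(T=4, tau=2, H=8, h=4, W=8, w=4, d_model=24)


@pytest.fixture
def random_clip_stack(rng, tiny_grid):
    return rng.random((4, tiny_grid.T, 3, tiny_grid.H, tiny_grid.W)).astype(np.float32)
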