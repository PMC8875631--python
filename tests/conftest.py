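import numpy as np
import pytest

from topovote import HardMask, MaskEnsemble, SoftMask


def random_hard_ensemble(rng, n, shape, p=0.5):
    return MaskEnsemble(
        [HardMask((rng.random(shape) < p).astype(np.uint8)) for _ in range(n)]
    )


def random_soft_ensemble(rng, n, shape):
    return MaskEnsemble([SoftMask(rng.random(shape)) for _ in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
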