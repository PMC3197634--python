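import numpy as np
import pytest

import msvscan as ms
from msvscan.profile import configure_length
from msvscan.striped import reduce_profile


@pytest.fixture(scope="session")
def model_mid():
    """Calibrated mid-size synthetic model shared by stats/pipeline tests."""
    core = ms.synthetic_profile(80, seed=3)
    sp = configure_length(core, 400)
    rp = reduce_profile(sp)
    cal = ms.calibrate(sp, rp=rp, n=200, Lcal=400, seed=1)
    return sp, rp, cal


@pytest.fixture(scope="session")
def model_170():
    """The canonical study model: M=170, entropy-weighted to 0.6 bits/pos."""
    core = ms.synthetic_profile(170, seed=11)
    sp = configure_length(core, 400)
    rp = reduce_profile(sp)
    cal = ms.calibrate(sp, rp=rp, n=200, Lcal=400, seed=7)
    return sp, rp, cal


def tiny_instance(trial: int, max_m: int = 5, max_l: int = 8):
    """A small random profile/sequence pair for enumeration oracles."""
    rng = np.random.default_rng(10_000 + trial)
    M = int(rng.integers(1, max_m + 1))
    L = int(rng.integers(1, max_l + 1))
    core = ms.synthetic_profile(M, seed=trial, entropy_target=None)
    sp = configure_length(core, L)
    seq = ms.sample_iid(L, seed=trial + 1)
    return sp, seq
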