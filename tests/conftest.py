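import numpy as np
import pytest

from dyntexseg import compute_dt_field, default_three_region_scene


@pytest.fixture(scope="session")
def three_region_scene():
    """One rendered default scene with ground truth (seed fixed)."""
    seq, labels = default_three_region_scene(seed=1)
    return seq, labels


@pytest.fixture(scope="session")
def scene_field(three_region_scene):
    """DT field over the first window of the default scene."""
    seq, _ = three_region_scene
    return compute_dt_field(seq, (0, 61), patch_side=5, n=4, stride=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
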