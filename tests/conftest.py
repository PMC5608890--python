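import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from memfuse.mechanics import MechanicalParameters
from memfuse.simulate import SceneConfig, generate_patch_scene


@pytest.fixture(scope="session")
def params():
    return MechanicalParameters()


@pytest.fixture(scope="session")
def noiseless_scene():
    """One noiseless, bleach-free 900 um^2 'follows' patch at 1.6% dilation.

    The canonical closed-loop fixture: every downstream measurement must
    recover its ground truth exactly.
    """
    cfg = SceneConfig(
        noise=(0.0, 0.0),
        bleach_rate=0.0,
        n_patches=1,
        patch_area_range=(900.0, 900.0),
        image_shape=(512, 512),
        patch_behavior_probs=(1.0, 0.0, 0.0),
        target_dilations=(0.016,),
        seed=3,
    )
    return generate_patch_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
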