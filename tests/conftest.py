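import numpy as np
import pytest

from fetalconn.atlas import RoiAtlas, make_default_atlas
from fetalconn.cohort import GrowthTruth, simulate_cohort


@pytest.fixture(scope="session")
def atlas16():
    return make_default_atlas(16, seed=7)


@pytest.fixture(scope="session")
def atlas70():
    return make_default_atlas(70, seed=0)


@pytest.fixture(scope="session")
def truth16(atlas16):
    return GrowthTruth.default(atlas16)


@pytest.fixture(scope="session")
def truth70(atlas70):
    return GrowthTruth.default(atlas70)


@pytest.fixture(scope="session")
def small_cohort(atlas16, truth16):
    """Eight default-noise subjects on the 16-region atlas."""
    return simulate_cohort(atlas16, truth16, n_subjects=8, seed=11)


@pytest.fixture()
def line_atlas():
    """Four collinear, equally spaced regions for geometry tests."""
    coords = np.array([[float(k) * 10.0, 0.0, 0.0] for k in range(4)])
    return RoiAtlas(
        region_id=np.arange(4),
        name=tuple(f"r{k}" for k in range(4)),
        lobe=np.array(["frontal", "parietal", "temporal", "occipital"]),
        hemisphere=np.array(["L", "L", "R", "R"]),
        coord_ref=coords,
    )
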