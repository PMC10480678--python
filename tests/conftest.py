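import numpy as np
import pytest

from petiq import CohortSpec, generate_cohort
from petiq.phantom import DESK_GRID_XY, DESK_SPACING, PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def desk_cohort():
    """The eight-phantom reference cohort at desk-scale resolution."""
    return generate_cohort(CohortSpec.desk())


@pytest.fixture(scope="session")
def small_phantom():
    """A light single phantom for unit tests (coarse grid, ~70 kg)."""
    return build_phantom(
        PhantomSpec(
            name="unit",
            height_m=1.75,
            weight_kg=75.0,
            grid_xy=DESK_GRID_XY,
            spacing=DESK_SPACING,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
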