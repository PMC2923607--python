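from __future__ import annotations

import numpy as np
import pytest

from jointale.foci import Direction, Focus, Space, StudyFoci
from jointale.grid import GridSpec, ellipsoid_mask
from jointale.kernel import KernelSpec


def make_focus(x, y, z, study="s1", condition="A", space=Space.TAL_NATIVE,
               direction=Direction.DEFICIT):
    return Focus(study, condition, space, float(x), float(y), float(z), direction)


def make_study(coords, study="s1", condition="A", direction=Direction.DEFICIT):
    return StudyFoci(
        study_id=study,
        condition=condition,
        direction=direction,
        foci=tuple(
            make_focus(x, y, z, study, condition, direction=direction)
            for x, y, z in coords
        ),
    )


@pytest.fixture
def toy_grid():
    """A 20^3-ish grid at 2 mm centred on the origin."""
    return GridSpec(voxel_size=2.0, x_range=(-19.0, 19.0), y_range=(-19.0, 19.0),
                    z_range=(-19.0, 19.0))


@pytest.fixture
def small_grid():
    """A very small grid for permutation determinism tests."""
    return GridSpec(voxel_size=4.0, x_range=(-20.0, 20.0), y_range=(-20.0, 20.0),
                    z_range=(-20.0, 20.0))


@pytest.fixture
def grid4():
    """The full analysis bounding box at 4 mm."""
    return GridSpec(voxel_size=4.0)


@pytest.fixture
def mask4(grid4):
    return ellipsoid_mask(grid4)


@pytest.fixture
def kernel():
    return KernelSpec()
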