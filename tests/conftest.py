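"""Shared fixtures: grids, schemes and small synthetic fields."""

import numpy as np
import pytest

from tvdti.io_gradients import VolumeGrid, default_scheme
from tvdti.phantom import (
    make_smooth_random_tensor_field,
    reference_phantom,
    synthesize_dwi,
)


@pytest.fixture(scope="session")
def scheme12():
    return default_scheme(12, bvalue=1000.0)


@pytest.fixture(scope="session")
def small_grid():
    return VolumeGrid(shape=(12, 10, 4), voxel_size=(1.0, 1.0, 2.5))


@pytest.fixture(scope="session")
def ref_phantom():
    """Reference phantom tensor field plus bundle label map (60x60x20)."""
    return reference_phantom()


@pytest.fixture(scope="session")
def smooth_field_dwi(scheme12):
    """Noise-free DWI synthesized from a smooth random tensor field.

    The field varies independently in all six element channels, so the
    direction images span the full six-dimensional signal subspace.
    """
    grid = VolumeGrid(shape=(40, 40, 4), voxel_size=(1.0, 1.0, 2.5))
    field = make_smooth_random_tensor_field(grid, seed=5)
    return field, synthesize_dwi(field, 1000.0, scheme12)
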