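import numpy as np
import pytest

from batlas import GridGeometry, PhantomSpec, QuantMap, make_phantom
from batlas.phantom import DeformationSpec


def small_spec(**overrides) -> PhantomSpec:
    """A reduced-size phantom for fast registration tests."""
    defaults = dict(
        geometry=GridGeometry((48, 32, 8), (1.0, 1.0, 2.0)),
        body_semi_axes=(20, 12),
        skin_thickness=1,
        sat_thickness=2,
        bone_offset_y=6,
        bone_half_length=13,
        bone_half_thickness=1,
        sbat_semi_axes=(8, 3, 3),
        lung_semi_axes=(3, 2),
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def base_phantom():
    """Default-geometry base phantom, seed 1."""
    return make_phantom(seed=1)


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(small_spec(), seed=1)


def constant_map(geometry, value, quantity="FF"):
    return QuantMap(geometry, np.full(geometry.shape, value, dtype=float), quantity)
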