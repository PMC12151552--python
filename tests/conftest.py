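"""Shared fixtures.

The 2959-atom benchmark box and its O(N^2) reference are session-scoped:
several accuracy tests reuse them, and the direct sum is the expensive part.
Cubature calibrations are memoized inside the library for the session, so
repeated pipeline runs at the same settings only pay once.
"""

import numpy as np
import pytest

import glst
from glst.core import GLSTConfig


@pytest.fixture(scope="session")
def box349():
    """349-atom neutral salt-water box (16 Å edge)."""
    return glst.build_salt_water_box(glst.table1_recipes(seed=3)[1])


@pytest.fixture(scope="session")
def box2959():
    """2959-atom neutral salt-water box (32 Å edge)."""
    return glst.build_salt_water_box(glst.table1_recipes(seed=11)[2])


@pytest.fixture(scope="session")
def oracle2959(box2959):
    return glst.direct_coulomb(box2959)


@pytest.fixture(scope="session")
def oracle349(box349):
    return glst.direct_coulomb(box349)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def config():
    return GLSTConfig()
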