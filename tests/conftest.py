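import dataclasses

import numpy as np
import pytest

from socketry.phantom import Cylinder, PhantomSpec, generate_pair


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A compact phantom for fast repeated pipeline runs."""
    return PhantomSpec(
        shape=(40, 32, 48),
        spacing=(0.2, 0.2, 0.2),
        geometry=Cylinder(2.0, 5.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pair(small_spec):
    return generate_pair(small_spec)


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    """The study-condition phantom: 3 mm x 10 mm cylindrical socket at
    0.2 mm voxels, noise SD 5, between-scan gain drift."""
    return PhantomSpec(seed=1)


def vary(spec: PhantomSpec, **changes) -> PhantomSpec:
    return dataclasses.replace(spec, **changes)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
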