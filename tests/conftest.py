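import numpy as np
import pytest

from domassembly.interactions import oracle_targets_from_structure
from domassembly.structure import extract_domains
from domassembly.synthetic import (make_multidomain_target,
                                   standard_fixture_specs)


@pytest.fixture(scope="session")
def fixture_specs():
    return standard_fixture_specs(0)


@pytest.fixture(scope="session")
def two_domain(fixture_specs):
    """(target, layout) of the standard two-domain helix-pair fixture."""
    return make_multidomain_target(fixture_specs["two_domain"])


@pytest.fixture(scope="session")
def three_domain(fixture_specs):
    return make_multidomain_target(fixture_specs["three_domain"])


@pytest.fixture(scope="session")
def two_chain(fixture_specs):
    return make_multidomain_target(fixture_specs["two_chain"])


@pytest.fixture(scope="session")
def two_domain_oracle(two_domain):
    target, layout = two_domain
    return oracle_targets_from_structure(target, layout, r_max=40.0)


@pytest.fixture(scope="session")
def two_domain_parts(two_domain):
    target, layout = two_domain
    return extract_domains(target, layout)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
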