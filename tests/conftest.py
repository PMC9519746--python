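import numpy as np
import pytest

from attnmorph.synthetic import FieldSpec, PhantomSpec, generate_phantom, \
    generate_smooth_field, make_registration_case


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_case():
    """16^3 registration case with known ground truth (session-cached)."""
    return make_registration_case(
        PhantomSpec((16, 16, 16), 2, 0.02, seed=3),
        FieldSpec((16, 16, 16), amplitude=2.0, smoothness=6.0, seed=3),
    )


@pytest.fixture(scope="session")
def phantom32():
    """32^3 phantom (session-cached)."""
    return generate_phantom(PhantomSpec((32, 32, 32), 3, 0.02, seed=1))


@pytest.fixture(scope="session")
def smooth_field32():
    return generate_smooth_field(FieldSpec((32, 32, 32), 3.0, 8.0, seed=1))
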