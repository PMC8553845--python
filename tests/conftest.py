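import numpy as np
import pytest

from pseudopupil.synthetic_eye import (
    HONEYBEE_FIELD,
    AcuityField,
    OpticsParams,
    build_eye,
)

#: eye extent margin (facets) that keeps the facet mosaic filling the default
#: rendered field of view even at off-centre poses
RENDER_MARGIN = 38


@pytest.fixture(scope="session")
def honeybee_eye_model():
    return build_eye(HONEYBEE_FIELD)


@pytest.fixture(scope="session")
def uniform_eye_model():
    return build_eye(AcuityField(dphi_min_deg=2.0))


@pytest.fixture(scope="session")
def render_eye_model():
    """Honeybee eye with a mosaic wide enough for full rendered frames."""
    return build_eye(HONEYBEE_FIELD, margin=RENDER_MARGIN)


@pytest.fixture(scope="session")
def default_optics():
    return OpticsParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
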