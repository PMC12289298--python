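import numpy as np
import pytest

from dyadmind.synthetic_data import default_roi_set, make_synthetic_leadfield


@pytest.fixture(scope="session")
def lead_field():
    return make_synthetic_leadfield()


@pytest.fixture(scope="session")
def roi_set(lead_field):
    return default_roi_set(lead_field.source_labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
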