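import numpy as np
import pytest

from retinatune.retina import Chromosome, Stage1Params
from retinatune.runner import ReferenceData, ReferenceSpec, make_reference_data


@pytest.fixture(scope="session")
def true_chromosome() -> Chromosome:
    return ReferenceSpec().chromosome


@pytest.fixture(scope="session")
def reference_data() -> ReferenceData:
    """The default scaled synthetic reference (noise-free), built once."""
    return make_reference_data(ReferenceSpec())


@pytest.fixture(scope="session")
def stage1_params() -> Stage1Params:
    return Stage1Params()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
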