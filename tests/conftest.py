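import numpy as np
import pytest

from spliceae import MotifModel, build_scheme, generate_dataset


@pytest.fixture(scope="session")
def acceptor_model():
    return MotifModel(site_type="acceptor", seed=0)


@pytest.fixture(scope="session")
def donor_model():
    return MotifModel(site_type="donor", seed=0)


@pytest.fixture(scope="session")
def small_dataset(acceptor_model):
    """100 positives + 100 negatives, 90-nt acceptor windows."""
    return generate_dataset(100, 100, acceptor_model)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(params=["dax", "eiip", "complementary", "enthalpy", "galois4"])
def scheme(request):
    return build_scheme(request.param)
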