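import warnings

import numpy as np
import pytest

from bhdsc.config import PipelineConfig
from bhdsc.params import BreathHoldProtocol, FieldParams
from bhdsc.phantom import PhantomLayout, generate_phantom
from bhdsc.pipeline import run_pipeline


@pytest.fixture(scope="session")
def fp7():
    return FieldParams.from_field(7)


@pytest.fixture(scope="session")
def fp3():
    return FieldParams.from_field(3)


@pytest.fixture(scope="session")
def protocol():
    return BreathHoldProtocol()


@pytest.fixture(scope="session")
def layout():
    return PhantomLayout.default()


@pytest.fixture(scope="session")
def phantom_clean(protocol, fp7):
    return generate_phantom(protocol, fp7, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def phantom_noisy(protocol, fp7):
    return generate_phantom(protocol, fp7, noise_sd=0.5, seed=11)


@pytest.fixture(scope="session")
def pipeline_clean(phantom_clean, layout):
    ts, _ = phantom_clean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(
            ts, layout.mask("artery"), layout.mask("vein"),
            PipelineConfig(detrend=False),
        )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
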