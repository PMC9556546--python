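import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import meiocross as mx
from meiocross import configs

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def params():
    """Default coarsening parameters (wild-type Col dosage)."""
    return mx.CoarseningParams()


@pytest.fixture
def mc_params():
    """Monte-Carlo profile: coarse but stable time step for large batches."""
    return mx.CoarseningParams(dt_safety=0.25)


@pytest.fixture
def karyotype():
    return configs.FEMALE_KARYOTYPE


@pytest.fixture
def small_karyotype():
    """Two short chromosomes, cheap to simulate."""
    return mx.Karyotype(
        (mx.Chromosome("chrA", 10.0, 20.0), mx.Chromosome("chrB", 8.0, 15.0))
    )
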