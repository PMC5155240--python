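import time

import pytest

from nsatcn import ModelParams, NdepProfile, SiteSpec, generate_forcing, load_table
from nsatcn.experiments import run_study

STUDY_SEED = 42


@pytest.fixture(scope="session")
def table():
    return load_table()


@pytest.fixture(scope="session")
def us_site():
    return SiteSpec("US-TF-00", 5, "USA", "temperate forest")


@pytest.fixture(scope="session")
def us_forcing(us_site):
    return generate_forcing(us_site, (1851, 2009),
                            NdepProfile("us_temperate_forest"), seed=STUDY_SEED)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def study_timing():
    return {}


@pytest.fixture(scope="session")
def study(study_timing):
    """Full paperlike factorial experiment: 8 sites × 159 years × 6 scenarios."""
    t0 = time.monotonic()
    result = run_study(seed=STUDY_SEED, n_sites=8)
    study_timing["elapsed_s"] = time.monotonic() - t0
    return result
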