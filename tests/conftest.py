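import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from translatome import synthetic as syn  # noqa: E402
from translatome.preprocess import compute_m_values  # noqa: E402


@pytest.fixture(scope="session")
def small_design():
    return syn.SimulationDesign(n_genes=120, seed=7)


@pytest.fixture(scope="session")
def small_transcripts(small_design):
    return syn.gen_transcripts(small_design)


@pytest.fixture(scope="session")
def small_experiment(small_design):
    truth = syn.assign_regulation(small_design)
    exp = syn.gen_array_experiment(small_design, truth)
    return exp, truth


@pytest.fixture(scope="session")
def small_m_values(small_experiment):
    exp, truth = small_experiment
    return compute_m_values(exp), truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
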