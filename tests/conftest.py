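import warnings

import pytest
from hypothesis import HealthCheck, settings

import phasecall as pc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_run():
    """The packaged 30-gene fixture run end-to-end with default config."""
    cm, truth = pc.fixture_counts()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fixture has < 50 genes for dispersion
        result = pc.run_pipeline(cm)
    return cm, truth, result


@pytest.fixture(scope="session")
def default_sim_run():
    """The headline simulation (5000 genes, 200 planted, FC 4, phi 0.05)."""
    cm, truth = pc.simulate_counts(pc.SimConfig())
    result = pc.run_pipeline(cm, dict(zip(truth["gene_id"], truth["biotype"])))
    return cm, truth, result
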