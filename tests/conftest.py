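import pytest

from lactoferm.netdef import default_network
from lactoferm.pipeline import run_pipeline
from lactoferm.synthetic_data import default_scenario, generate


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture(scope="session")
def scenario_bundle(tmp_path_factory):
    """The default synthetic study, generated once per session."""
    outdir = tmp_path_factory.mktemp("scenario")
    return generate(default_scenario(seed=42), outdir)


@pytest.fixture(scope="session")
def pipeline_result(scenario_bundle):
    """Full inference chain run on the default synthetic study."""
    return run_pipeline(scenario_bundle.outdir)
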