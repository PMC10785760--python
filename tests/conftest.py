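import warnings

import pytest

from dioxome.pipeline import PipelineConfig, run_pipeline
from dioxome.synthetic import SimConfig, generate_study


@pytest.fixture(scope="session")
def study():
    """Default-scale synthetic study, seed 1."""
    return generate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default pipeline run, seed 1 (shared across tests)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(PipelineConfig(seed=1))
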