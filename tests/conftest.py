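import pytest

from periharm import Pipeline, PipelineConfig
from periharm.lexicons import load_lexicons


@pytest.fixture(scope="session")
def pipeline() -> Pipeline:
    return Pipeline(PipelineConfig())


@pytest.fixture(scope="session")
def lexicons():
    return load_lexicons()
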