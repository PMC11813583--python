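import pytest

from fragrescue import ModelParams


@pytest.fixture(scope="session")
def ref_params() -> ModelParams:
    """Reference beta-lactamase parameter set used throughout."""
    return ModelParams.reference()
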