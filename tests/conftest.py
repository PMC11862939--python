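import pytest

from cagereactor import models


@pytest.fixture
def pair_model_4a5():
    """Five-species pairwise-inclusion model at the 1:2:2 mixture (M)."""
    return models.pair_binding_model("4a", "5", 2e-3, 4e-3, 4e-3)


@pytest.fixture
def pair_model_4b5():
    """Five-species model for the reactive azide/alkyne pair at 1:1:2 (M)."""
    return models.pair_binding_model("4b", "5", 2e-3, 2e-3, 4e-3)
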