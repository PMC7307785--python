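import numpy as np
import pytest

from cldyn import build_default_model
from cldyn.calibration import tune_leaks


@pytest.fixture(scope="session")
def tuned_model():
    """A leak-tuned default model (session-scoped; treat as read-only)."""
    model = build_default_model()
    tune_leaks(model, refine=False)
    return model


@pytest.fixture
def make_tuned_model():
    """Factory for a fresh tuned model that a test may mutate."""

    def _make(overrides=None, refine=False):
        model = build_default_model(overrides)
        tune_leaks(model, refine=refine)
        return model

    return _make
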