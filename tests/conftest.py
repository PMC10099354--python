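import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


class StubPredictor:
    """Duck-typed predictor applying a per-patch function (tests only)."""

    def __init__(self, fn):
        self.fn = fn

    def predict_batch(self, patches):
        return np.stack([self.fn(p) for p in patches])

    def predict(self, patch):
        return self.fn(patch)


@pytest.fixture
def make_stub():
    return StubPredictor
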