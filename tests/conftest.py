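import numpy as np
import pytest

from cfrsim import BehaviorModel, Reply, ResponseRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def synthetic_model():
    return BehaviorModel.synthetic()


@pytest.fixture
def small_records():
    """Tiny record set with known category frequencies (2 accept, 1 reject, 1 not-seen)."""
    return [
        ResponseRecord(10.0, Reply.ACCEPT),
        ResponseRecord(45.0, Reply.ACCEPT),
        ResponseRecord(20.0, Reply.REJECT),
        ResponseRecord(float("inf"), Reply.NOT_SEEN),
    ]
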