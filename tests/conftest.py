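import numpy as np
import pytest

import criticality as ca

#: operating point of the synthetic study conditions (see docs/methods.md)
BLOB_SCALE = 0.0075


@pytest.fixture(scope="session")
def blob_dataset():
    """3-class, 40/class, 4-attribute magnitude-ordered blobs (fixed seed)."""
    return ca.make_blobs(n_classes=3, n_per_class=40, n_features=4,
                         separation=6.0, seed=1)


@pytest.fixture(scope="session")
def short_schedule():
    return ca.ClampSchedule(steps_per_sample=1000, step_size=0.1,
                            transient_fraction=0.5, record_stride=10)


@pytest.fixture
def spec4():
    return ca.NetworkSpec(model="berry", n_oscillators=4, weights=0.0005,
                          input_map=(0, 1, 2, 3))
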