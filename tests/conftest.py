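import numpy as np
import pytest

from epiphos.design import Contrast, Sample, SampleDesign


@pytest.fixture
def two_group_design() -> SampleDesign:
    """One plex, 4 mock vs 4 pilocarpine (no untreated channels)."""
    samples = [Sample(f"M{i}", "4h", "mock", 4.0, i) for i in range(1, 5)] + [
        Sample(f"P{i}", "4h", "pilocarpine", 4.0, i) for i in range(1, 5)
    ]
    return SampleDesign(samples)


@pytest.fixture
def pm4_contrast() -> Contrast:
    return Contrast("P/M(4h)", "4h", "pilocarpine", "mock")


@pytest.fixture
def full_design() -> SampleDesign:
    return SampleDesign.default()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
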