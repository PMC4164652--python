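import numpy as np
import pytest

from sbpseg.segmentation import SegmentationConfig, default_critical_curve


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_curve():
    """The packaged Monte-Carlo critical curve (alpha=0.01, l0=33)."""
    return default_critical_curve()


@pytest.fixture(scope="session")
def default_config(default_curve):
    return SegmentationConfig(alpha=0.01, l0=33, critical_curve=default_curve)
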