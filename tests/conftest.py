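import numpy as np
import pytest

from perfquant.config import StudyConfig
from perfquant.signal_model import AIF_SEQ, IMAGING_SEQ, PD_SEQ, RelaxationContext


@pytest.fixture
def cfg() -> StudyConfig:
    return StudyConfig()


@pytest.fixture
def ctx() -> RelaxationContext:
    return RelaxationContext()


@pytest.fixture
def imaging_seq():
    return IMAGING_SEQ


@pytest.fixture
def aif_seq():
    return AIF_SEQ


@pytest.fixture
def pd_seq():
    return PD_SEQ


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
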