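import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pttquant.ptt import Condition, SampleMeasurement
from pttquant.sim import demo_config, demo_design

settings.register_profile(
    "ci", deadline=None, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def design():
    return demo_design("testgene")


@pytest.fixture
def sim_config():
    return demo_config(seed=7)


def make_measurement(
    P1,
    P3,
    gene="g",
    condition=Condition.MET_MINUS,
    timepoint_h=0.0,
    cleaved=True,
    P2=float("nan"),
):
    return SampleMeasurement(
        gene=gene,
        condition=condition,
        timepoint_h=timepoint_h,
        cleaved=cleaved,
        P1=P1,
        P2=P2,
        P3=P3,
    )
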