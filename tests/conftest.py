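import pytest

from painrescale import SCALE_0_100, ArmSummary, ScaleDefinition


@pytest.fixture
def scale_100():
    return SCALE_0_100


@pytest.fixture
def scale_10():
    return ScaleDefinition("NRS-10", 0, 10)


@pytest.fixture
def scale_4pt():
    return ScaleDefinition("VRS-4", 0, 3)


@pytest.fixture
def scale_5pt():
    return ScaleDefinition("VRS-5", 0, 4)


def make_arm(
    arm="A",
    scale=SCALE_0_100,
    n=50,
    mean=40.0,
    sd=20.0,
    trial="t1",
    comparison="c1",
    timepoint="tp1",
    **kw,
):
    return ArmSummary(
        trial_id=trial,
        comparison_id=comparison,
        timepoint=timepoint,
        arm=arm,
        scale=scale,
        n=n,
        mean=mean,
        sd=sd,
        **kw,
    )


@pytest.fixture
def arm_factory():
    return make_arm
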