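import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from multiarm.design_model import (Arm, DesignSpec, Hypothesis, Stage,
                                   StageTrigger, flair_design)

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def flair():
    return flair_design()


@pytest.fixture(scope="session")
def two_arm_spec():
    """Minimal single-stage two-arm design for degenerate-case tests."""
    return DesignSpec(
        name="mini",
        arms=(Arm("C", "control", 4.5, 0.1), Arm("E", "experimental", 6.0, 0.2)),
        stages=(Stage(1, ("C", "E"), (1, 1),
                      StageTrigger("arm_recruitment", arm="E", count=50)),),
        hypotheses=(Hypothesis(label="e-vs-c", experimental_arm="E", control_arm="C",
                               endpoint="time_to_event", control_median=4.5,
                               experimental_median=6.0, accrual_years=1.0,
                               min_followup_years=2.0, dropout_prob=0.05,
                               interim_fractions=(1.0,)),),
        stratification_factors=(("site", ("a", "b")), ("sex", ("m", "f"))),
        accrual_rate=100.0,
    ).check()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
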