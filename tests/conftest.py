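import pytest

from opikin.ontology import Step
from opikin.simulate import (
    CaseJitter,
    CohortSpec,
    GeneratorConfig,
    OperatorSpec,
    StepProfile,
    simulate_case,
)


def small_config(seed: int = 0, steps=None, jitter: CaseJitter | None = None, **profile_kw):
    """A one-operator, two-step config small enough for per-test simulation."""
    kw = dict(duration_median_s=20.0, duration_log_sd=0.1)
    kw.update(profile_kw)
    steps = steps or (Step.DISSECTION, Step.HAND_SEWN_ANASTOMOSIS)
    profiles = {s: StepProfile(**kw) for s in steps}
    ops = [OperatorSpec("surg1", "attending", 500)]
    return GeneratorConfig(
        cohorts=[CohortSpec("solo", profiles, 1, ops)],
        sample_rate_hz=25.0,
        seed=seed,
        jitter=jitter or CaseJitter(),
    )


@pytest.fixture
def small_case():
    return simulate_case(small_config(seed=1), "solo", 0)
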