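import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_cohort():
    """A tiny 2x2x2 cohort exercising every factor level."""
    from lifespans import Cohort, LifespanRecord

    recs = []
    ages = iter([820.0, 870.0, 760.0, 900.0, 1010.0, 980.0, 840.0, 855.0])
    i = 0
    for genotype in ("control", "dwarf"):
        for treatment in ("saline", "GH"):
            for sex in ("male", "female"):
                i += 1
                recs.append(
                    LifespanRecord(
                        animal_id=f"m{i}",
                        age_days=next(ages),
                        genotype=genotype,
                        treatment=treatment,
                        sex=sex,
                    )
                )
    return Cohort(tuple(recs), protocol_label="unit")
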