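import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from msprev import SurveyIndividual


def make_individual(person_id="P1", province_id=1, age=50.0, sex=0,
                    sampling_weight=1.0, **clinical):
    """A respondent with every clinical field observed unless overridden."""
    defaults = dict(
        fasting_glucose=100.0, self_report_diabetes=0, bmi=25.0,
        sbp=120.0, dbp=75.0, hta_treatment=0, ldl=90.0,
        cvr_category="moderate_cvr",
    )
    defaults.update(clinical)
    return SurveyIndividual(
        person_id=person_id, province_id=province_id, age=age, sex=sex,
        sampling_weight=sampling_weight, **defaults,
    )


@pytest.fixture
def individual_factory():
    return make_individual


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
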