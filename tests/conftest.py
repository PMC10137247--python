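import pytest
from hypothesis import HealthCheck, settings

from rwemcda import FeasibilityChecklist, default_criterion_set

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # factory fixtures below are stateless, so sharing across examples is fine
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("deterministic")


@pytest.fixture
def default_set():
    return default_criterion_set()


@pytest.fixture
def make_checklist():
    """Factory for a benign checklist with targeted overrides."""

    def factory(**overrides) -> FeasibilityChecklist:
        base = dict(
            n_standard_of_care_options=1,
            soc_evolving=False,
            patient_volume="high",
            required_sample_size=100,
            annual_accruable_patients=50.0,
            followup_needed_years=1.0,
            remaining_patent_years=10.0,
            missing_eligibility_characteristics=False,
            n_missing_covariates=0,
            can_identify_primary_treatment_line=True,
            can_identify_prior_subsequent_treatment_line=True,
            expertise_available=True,
            methods_available=True,
        )
        base.update(overrides)
        return FeasibilityChecklist(**base)

    return factory
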