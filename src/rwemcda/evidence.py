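"""Structured evidence carried by one RWE-question proposal.

An :class:`EvidenceProfile` bundles everything the rule engines consume:
survival evidence (hazard ratios and median gains, with optional confidence
intervals), the economic evidence (ICER point estimate and assessed range,
$/QALY), a feasibility checklist, and any expert-asserted ratings for the
qualitative criteria.  Units are months for survival quantities and years
for accrual/follow-up/patent horizons.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class Endpoint(str, Enum):
    OVERALL_SURVIVAL = "overall_survival"
    PROGRESSION_FREE_SURVIVAL = "progression_free_survival"


class PatientVolume(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class SurvivalEvidence(BaseModel):
    """One survival comparison versus standard of care.

    ``baseline_median_months`` is the control-arm median and selects, for
    overall survival, which threshold form applies (short- vs long-survival
    diseases).  ``point_estimate_months`` with its confidence interval feeds
    the uncertainty quantification, not the benefit rating.
    """

    model_config = ConfigDict(frozen=True)

    endpoint: Endpoint
    hazard_ratio: float = Field(gt=0)
    median_gain_months: float = Field(ge=0)
    baseline_median_months: float = Field(gt=0)
    point_estimate_months: Optional[float] = Field(default=None, gt=0)
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None

    @model_validator(mode="after")
    def _check_ci(self) -> "SurvivalEvidence":
        ci = (self.ci_lower, self.ci_upper)
        if any(v is not None for v in ci):
            if any(v is None for v in ci) or self.point_estimate_months is None:
                raise ValueError(
                    "ci_lower, ci_upper and point_estimate_months must be "
                    "given together"
                )
            if not (self.ci_lower <= self.point_estimate_months <= self.ci_upper):
                raise ValueError(
                    "confidence interval must bracket the point estimate"
                )
        return self

    @property
    def has_ci(self) -> bool:
        return self.ci_lower is not None


class EconomicEvidence(BaseModel):
    """ICER point estimate and the assessed upper/lower range ($/QALY)."""

    model_config = ConfigDict(frozen=True)

    icer_base: float = Field(gt=0)
    icer_lower: float
    icer_upper: float

    @model_validator(mode="after")
    def _check_range(self) -> "EconomicEvidence":
        if not (self.icer_lower <= self.icer_base <= self.icer_upper):
            raise ValueError("ICER range must bracket the base case")
        return self


class FeasibilityChecklist(BaseModel):
    """Semi-quantitative inputs for the Group B (feasibility) criteria."""

    model_config = ConfigDict(frozen=True)

    # comparator
    n_standard_of_care_options: int = Field(ge=0)
    soc_evolving: bool = False
    patient_volume: PatientVolume = PatientVolume.MODERATE
    # cases / reasonable time
    required_sample_size: int = Field(gt=0)
    annual_accruable_patients: float = Field(gt=0)
    followup_needed_years: float = Field(ge=0)
    remaining_patent_years: float = Field(gt=0)
    # data
    missing_eligibility_characteristics: bool = False
    n_missing_covariates: int = Field(ge=0, default=0)
    can_identify_primary_treatment_line: bool = True
    can_identify_prior_subsequent_treatment_line: bool = True
    # expertise & methodology
    expertise_available: bool = True
    methods_available: bool = True


class EvidenceProfile(BaseModel):
    """All evidence attached to one proposed RWE question.

    The benefit criterion needs either survival evidence, the
    ``alternative_outcome_benefit_only`` flag (benefit shown only in response
    rate / quality of life / another outcome), or an expert-asserted rating.
    ``expert_ratings`` supplies ratings for qualitative criteria; entries
    listed in ``expert_overrides`` replace rule-derived ratings as well.
    """

    model_config = ConfigDict(frozen=True)

    proposal_id: str
    survival: tuple[SurvivalEvidence, ...] = ()
    alternative_outcome_benefit_only: bool = False
    economic: Optional[EconomicEvidence] = None
    feasibility: FeasibilityChecklist
    expert_ratings: dict[str, int] = {}
    expert_overrides: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "EvidenceProfile":
        for cid, r in self.expert_ratings.items():
            if r not in (1, 2, 3):
                raise ValueError(
                    f"expert rating for {cid!r} must be in {{1, 2, 3}}, got {r!r}"
                )
        if (
            not self.survival
            and not self.alternative_outcome_benefit_only
            and "benefit" not in self.expert_ratings
        ):
            raise ValueError(
                "benefit needs survival evidence, the alternative-outcome "
                "flag, or an expert rating"
            )
        unknown = set(self.expert_overrides) - set(self.expert_ratings)
        if unknown:
            raise ValueError(
                f"expert_overrides without expert_ratings: {sorted(unknown)}"
            )
        return self
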