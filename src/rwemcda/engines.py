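"""Rule engines mapping structured evidence to 3-point criterion ratings.

Benefit (criterion 1) follows a graded clinical-benefit rubric keyed on the
hazard ratio and the gain in median survival, with separate overall-survival
forms for short-survival (control median <= 12 months) and long-survival
(> 12 months) diseases and a progression-free-survival clause capped at the
middle rating.  Uncertainty (criterion 2) converts relative interval width
(survival CI or assessed ICER range) into three bands: < 10 % variation,
10-25 %, > 25 %.  The Group B criteria are deterministic checklist rubrics,
including the reasonable-time rule: an RWE study is timely if accrual plus
follow-up takes less than half the remaining patent life.

Boundary conventions (rating 3 thresholds, inclusive/exclusive choices) are
documented per function and in the methods note; printed strict inequalities
on the hazard ratio are honored strictly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

from .criteria import CriterionSet, MeasureKind, Provenance, RatingVector
from .errors import RatingError
from .evidence import (
    Endpoint,
    EvidenceProfile,
    FeasibilityChecklist,
    PatientVolume,
    SurvivalEvidence,
)

# Benefit-rubric thresholds. One year = 12.0 months; a baseline of exactly
# 12 months uses the short-survival form (the long form is printed strictly
# "> 1 year").
OS_SHORT_BASELINE_MAX_MONTHS = 12.0
OS_SHORT_HR_MAX = 0.65
OS_SHORT_GAIN_MID_MONTHS = 2.5   # gain in [2.5, 3.0) -> rating 2
OS_SHORT_GAIN_TOP_MONTHS = 3.0   # gain >= 3.0 -> rating 3
OS_LONG_HR_MAX = 0.70
OS_LONG_GAIN_MID_MONTHS = 3.0    # gain in [3.0, 5.0) -> rating 2
OS_LONG_GAIN_TOP_MONTHS = 5.0    # gain >= 5.0 -> rating 3
PFS_HR_MAX = 0.65
PFS_GAIN_MIN_MONTHS = 1.5        # gain strictly > 1.5 -> rating 2 (PFS caps at 2)

# Uncertainty bands on relative variation; the middle band is closed at both
# ends ("10-25 %"), the outer bands open.
UNCERTAINTY_LOW_MAX = 0.10
UNCERTAINTY_HIGH_MAX = 0.25

#: A study is timely if it completes within this fraction of remaining patent life.
REASONABLE_TIME_PATENT_FRACTION = 0.5

_VOLUME_SUBSCORE = {
    PatientVolume.LOW: 1,
    PatientVolume.MODERATE: 2,
    PatientVolume.HIGH: 3,
}


@dataclass(frozen=True)
class RatingResult:
    """A rating together with the clause that produced it."""

    rating: int
    rationale: str


def _rate_survival_item(ev: SurvivalEvidence) -> RatingResult:
    hr, gain = ev.hazard_ratio, ev.median_gain_months
    if ev.endpoint is Endpoint.PROGRESSION_FREE_SURVIVAL:
        if hr < PFS_HR_MAX and gain > PFS_GAIN_MIN_MONTHS:
            return RatingResult(2, f"PFS HR {hr} < {PFS_HR_MAX} with gain "
                                   f"{gain} > {PFS_GAIN_MIN_MONTHS} mo")
        return RatingResult(1, f"PFS evidence below the moderate-benefit bar "
                               f"(HR {hr}, gain {gain} mo)")
    if ev.baseline_median_months <= OS_SHORT_BASELINE_MAX_MONTHS:
        hr_max, mid, top, form = (
            OS_SHORT_HR_MAX, OS_SHORT_GAIN_MID_MONTHS,
            OS_SHORT_GAIN_TOP_MONTHS, "short-survival (baseline <= 1 yr)",
        )
    else:
        hr_max, mid, top, form = (
            OS_LONG_HR_MAX, OS_LONG_GAIN_MID_MONTHS,
            OS_LONG_GAIN_TOP_MONTHS, "long-survival (baseline > 1 yr)",
        )
    if hr < hr_max and gain >= top:
        return RatingResult(3, f"OS {form}: HR {hr} < {hr_max}, gain "
                               f"{gain} >= {top} mo")
    if hr < hr_max and gain >= mid:
        return RatingResult(2, f"OS {form}: HR {hr} < {hr_max}, gain {gain} "
                               f"in [{mid}, {top}) mo")
    return RatingResult(1, f"OS {form}: below the moderate-benefit bar "
                           f"(HR {hr}, gain {gain} mo)")


def rate_benefit(profile: EvidenceProfile) -> RatingResult:
    """Rate the drug's perceived incremental benefit (criterion 1).

    Each piece of survival evidence is rated by its clause and the maximum
    governs (the rubric's clauses are disjunctive).  Benefit shown only in an
    alternative outcome (response rate, quality of life...) is rated 1.
    Falls back to an expert-asserted rating when no quantitative evidence is
    available.
    """
    results = [_rate_survival_item(ev) for ev in profile.survival]
    if profile.alternative_outcome_benefit_only:
        results.append(
            RatingResult(1, "benefit demonstrated only in an alternative "
                            "outcome (response rate / QoL / other)")
        )
    if results:
        return max(results, key=lambda r: r.rating)
    expert = profile.expert_ratings.get("benefit")
    if expert is not None:
        return RatingResult(expert, "expert-asserted benefit rating")
    raise RatingError("benefit unratable: no usable evidence and no expert rating")


def uncertainty_variation(profile: EvidenceProfile) -> float:
    """Relative variation of the most uncertain quantitative source.

    Survival sources contribute CI width over the point estimate; the
    economic source contributes ICER range width over the base case.  The
    maximum over all available sources governs: a question is as uncertain
    as its most uncertain quantity.
    """
    variations: list[float] = []
    for ev in profile.survival:
        if ev.has_ci:
            variations.append(
                (ev.ci_upper - ev.ci_lower) / ev.point_estimate_months
            )
    if profile.economic is not None:
        econ = profile.economic
        variations.append((econ.icer_upper - econ.icer_lower) / econ.icer_base)
    if not variations:
        raise RatingError("no quantitative uncertainty source")
    return max(variations)


def rate_uncertainty(
    variation: Optional[float] = None,
    expert_rating: Optional[int] = None,
) -> int:
    """Rate magnitude of uncertainty (criterion 2).

    Quantitative bands: variation < 10 % -> 1, 10-25 % (closed) -> 2,
    > 25 % -> 3.  The quantitative result is used when available; otherwise
    the expert's qualitative rating.
    """
    if variation is not None:
        if variation < 0:
            raise RatingError("variation must be non-negative")
        if variation < UNCERTAINTY_LOW_MAX:
            return 1
        if variation <= UNCERTAINTY_HIGH_MAX:
            return 2
        return 3
    if expert_rating is not None:
        return expert_rating
    raise RatingError("uncertainty unratable: no variation and no expert rating")


def rate_comparator(fc: FeasibilityChecklist) -> int:
    """Rate comparator feasibility (criterion 4): worst of SOC clarity and volume.

    Standard-of-care subscore: more than two options or an evolving standard
    (or none at all) -> 1; exactly two -> 2; one stable standard -> 3.  The
    'and/or' coupling with patient volume is read as worst-governs: a fatal
    problem in either dimension caps the rating.
    """
    n = fc.n_standard_of_care_options
    if fc.soc_evolving or n > 2 or n == 0:
        soc = 1
    elif n == 2:
        soc = 2
    else:
        soc = 3
    return min(soc, _VOLUME_SUBSCORE[fc.patient_volume])


class ReasonableTime(NamedTuple):
    accrual_years: float
    total_years: float
    reasonable: bool


def reasonable_time_years(fc: FeasibilityChecklist) -> ReasonableTime:
    """Accrual and total study duration, and whether the study is timely.

    Timely means accrual plus follow-up completes in under half the
    remaining patent life.
    """
    if fc.annual_accruable_patients <= 0:
        raise RatingError("invalid accrual rate")
    accrual = fc.required_sample_size / fc.annual_accruable_patients
    total = accrual + fc.followup_needed_years
    window = REASONABLE_TIME_PATENT_FRACTION * fc.remaining_patent_years
    return ReasonableTime(accrual, total, total < window)


def rate_cases(fc: FeasibilityChecklist) -> int:
    """Rate case accrual feasibility (criterion 5).

    3 if accrual plus follow-up fits the reasonable-time window, 2 if
    accrual alone fits but follow-up pushes past it, 1 if even accrual does
    not fit.
    """
    rt = reasonable_time_years(fc)
    if rt.reasonable:
        return 3
    window = REASONABLE_TIME_PATENT_FRACTION * fc.remaining_patent_years
    if rt.accrual_years < window:
        return 2
    return 1


def rate_data(fc: FeasibilityChecklist) -> int:
    """Rate data availability (criterion 6).

    Substantial concern (1): eligibility-defining characteristics missing,
    more than two covariates missing, or the primary treatment line cannot
    be identified.  Moderate concern (2): one or two covariates missing or
    prior/subsequent treatment lines unidentifiable.  Otherwise 3.
    """
    if (
        fc.missing_eligibility_characteristics
        or fc.n_missing_covariates > 2
        or not fc.can_identify_primary_treatment_line
    ):
        return 1
    if (
        1 <= fc.n_missing_covariates <= 2
        or not fc.can_identify_prior_subsequent_treatment_line
    ):
        return 2
    return 3


def rate_expertise_methodology(fc: FeasibilityChecklist) -> int:
    """Rate availability of expertise and methods (criterion 7)."""
    return 1 + fc.expertise_available + fc.methods_available


# ---------------------------------------------------------------------------
# dispatch over a criterion set
# ---------------------------------------------------------------------------

def _rule_rating(profile: EvidenceProfile, criterion_id: str) -> Optional[RatingResult]:
    """Rule-derived rating for a criterion, or None if no quantitative route."""
    fc = profile.feasibility
    if criterion_id == "benefit":
        if profile.survival or profile.alternative_outcome_benefit_only:
            return rate_benefit(profile)
        return None
    if criterion_id == "magnitude_of_uncertainty":
        try:
            variation = uncertainty_variation(profile)
        except RatingError:
            return None
        return RatingResult(
            rate_uncertainty(variation),
            f"relative variation {variation:.3f}",
        )
    if criterion_id == "comparator":
        return RatingResult(rate_comparator(fc), "comparator checklist")
    if criterion_id == "cases":
        return RatingResult(rate_cases(fc), "reasonable-time rule")
    if criterion_id == "data":
        return RatingResult(rate_data(fc), "data checklist")
    if criterion_id == "expertise_and_methodology":
        return RatingResult(rate_expertise_methodology(fc), "expertise checklist")
    return None


def rate_all(profile: EvidenceProfile, cset: CriterionSet) -> RatingVector:
    """Rate every criterion of ``cset``, recording provenance per criterion.

    Quantitatively measurable criteria go through their rule engines;
    qualitative criteria (and any criterion without quantitative inputs)
    take the profile's expert rating.  An expert rating replaces a
    rule-derived one only when the criterion id is listed in the profile's
    ``expert_overrides``.
    """
    ratings: dict[str, int] = {}
    provenance: dict[str, Provenance] = {}
    for criterion in cset.criteria:
        cid = criterion.id
        expert = profile.expert_ratings.get(cid)
        result = _rule_rating(profile, cid)
        if result is not None and cid not in profile.expert_overrides:
            ratings[cid] = result.rating
            provenance[cid] = Provenance.RULE_DERIVED
        elif expert is not None:
            ratings[cid] = expert
            provenance[cid] = Provenance.EXPERT_ASSERTED
        elif criterion.measure_kind is MeasureKind.QUALITATIVE_EXPERT or result is None:
            if criterion.measure_kind is MeasureKind.QUALITATIVE_EXPERT:
                raise RatingError(
                    f"incomplete rating: missing expert rating for {cid!r}"
                )
            raise RatingError(f"unratable criterion: {cid!r}")
    return RatingVector(
        proposal_id=profile.proposal_id, ratings=ratings, provenance=provenance
    )
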