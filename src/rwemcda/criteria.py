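"""Criterion taxonomy, versioned criterion sets, weights, and rating vectors.

The rating rubric scores a proposed real-world-evidence (RWE) question on
seven criteria split into two groups: Group A judges how *important* the
question is (perceived clinical benefit of the drug, magnitude of the
uncertainty, relevance of resolving it to decision-makers) and Group B
judges how *feasible* an RWE analysis would be (comparator identification,
case accrual, data availability, expertise and methodology).  Each criterion
is rated on a 3-point scale (3 = high performance) and carries a percent
weight; the weights of a set always sum to 100.

Three versioned sets are shipped:

``v2_final7``
    The final seven-criterion instrument with its published weights.
``v1_table1_9``
    The nine-criterion intermediate set (impact-of-uncertainty still present,
    expertise and methodology still separate).  No weights were published for
    it; an equal split is used.
``v0_draft10``
    The ten-criterion draft including the later-removed "Time" criterion.
    Reconstructed by name only; descriptions are approximate.

Structural edits (:func:`remove_criterion`, :func:`merge_criteria`) return new
sets and preserve the sum-to-100 invariant: removal rescales the survivors
proportionally, merging pools the pair's weights additively.
"""

from __future__ import annotations

import json
from enum import Enum
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import CriterionSetError

#: Weights are percentages; a valid set sums to this.
TOTAL_WEIGHT = 100.0
#: Absolute tolerance on the sum-to-100 invariant.
WEIGHT_TOL = 1e-9

RATING_LEVELS = (1, 2, 3)


class Group(str, Enum):
    """Criterion group: importance of the question vs. feasibility of answering it."""

    A_IMPORTANCE = "A_importance"
    B_FEASIBILITY = "B_feasibility"


class MeasureKind(str, Enum):
    QUANTITATIVE_RULE = "quantitative_rule"
    SEMI_QUANTITATIVE_CHECKLIST = "semi_quantitative_checklist"
    QUALITATIVE_EXPERT = "qualitative_expert"


class Provenance(str, Enum):
    RULE_DERIVED = "rule_derived"
    EXPERT_ASSERTED = "expert_asserted"


class Criterion(BaseModel):
    """One rubric criterion with its three rating-level descriptors."""

    model_config = ConfigDict(frozen=True)

    id: str
    name: str
    group: Group
    description: str = ""
    rating_levels: dict[int, str]
    measure_kind: MeasureKind

    @field_validator("rating_levels")
    @classmethod
    def _exactly_three_levels(cls, v: dict[int, str]) -> dict[int, str]:
        if set(v) != set(RATING_LEVELS):
            raise ValueError("rating_levels must have exactly the keys 1, 2, 3")
        return dict(v)


class CriterionSet(BaseModel):
    """An ordered, versioned collection of criteria with percent weights.

    Invariants (enforced at construction): every criterion id carries exactly
    one weight and vice versa, all weights are strictly positive, and the
    weights sum to 100 within ``WEIGHT_TOL``.  Weights are stored at full
    precision; round only for display.
    """

    model_config = ConfigDict(frozen=True)

    version_tag: str
    criteria: tuple[Criterion, ...]
    weights: dict[str, float]

    @model_validator(mode="after")
    def _check_invariants(self) -> "CriterionSet":
        ids = [c.id for c in self.criteria]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate criterion id")
        if set(self.weights) != set(ids):
            raise ValueError("weights and criteria must cover the same ids")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all weights must be strictly positive")
        total = sum(self.weights.values())
        if abs(total - TOTAL_WEIGHT) > WEIGHT_TOL:
            raise ValueError(f"weights must sum to {TOTAL_WEIGHT}, got {total!r}")
        return self

    # -- lookups ---------------------------------------------------------

    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    def criterion(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise CriterionSetError(f"criterion not found: {criterion_id!r}")

    def weight(self, criterion_id: str) -> float:
        if criterion_id not in self.weights:
            raise CriterionSetError(f"criterion not found: {criterion_id!r}")
        return self.weights[criterion_id]

    def group_of(self, criterion_id: str) -> Group:
        return self.criterion(criterion_id).group

    def ids_in_group(self, group: Group) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria if c.group is group)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")

    @classmethod
    def from_dict(cls, data: dict) -> "CriterionSet":
        return cls.model_validate(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CriterionSet":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CriterionSet":
        return cls.from_dict(json.loads(text))


class RatingVector(BaseModel):
    """The per-criterion 3-point ratings for one proposal.

    ``provenance`` records, per criterion, whether the rating came out of a
    quantitative rule engine or was asserted by an expert.
    """

    model_config = ConfigDict(frozen=True)

    proposal_id: str
    ratings: dict[str, int]
    provenance: dict[str, Provenance]
    rater_id: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "RatingVector":
        for cid, r in self.ratings.items():
            if r not in RATING_LEVELS:
                raise ValueError(
                    f"rating for {cid!r} must be in {{1, 2, 3}}, got {r!r}"
                )
        if set(self.provenance) != set(self.ratings):
            raise ValueError("provenance must cover exactly the rated criteria")
        return self

    @classmethod
    def from_ratings(
        cls,
        proposal_id: str,
        ratings: dict[str, int],
        provenance: Optional[dict[str, Provenance]] = None,
        rater_id: Optional[str] = None,
    ) -> "RatingVector":
        """Build a vector, defaulting provenance to expert-asserted."""
        if provenance is None:
            provenance = {cid: Provenance.EXPERT_ASSERTED for cid in ratings}
        return cls(
            proposal_id=proposal_id,
            ratings=ratings,
            provenance=provenance,
            rater_id=rater_id,
        )

    def bound_to(self, cset: CriterionSet) -> bool:
        """Whether this vector covers exactly the ids of ``cset``."""
        return set(self.ratings) == set(cset.ids())


# ---------------------------------------------------------------------------
# shipped criterion sets
# ---------------------------------------------------------------------------

_CONCERN_LEVELS = {1: "Substantial concern", 2: "Moderate concern", 3: "Low concern"}

_BENEFIT = Criterion(
    id="benefit",
    name="Drug's perceived incremental benefit",
    group=Group.A_IMPORTANCE,
    description=(
        "Perceived net clinical benefit of the therapy versus existing "
        "options, judged from available trial evidence or indirect "
        "comparisons using a graded clinical-benefit rubric (hazard ratios "
        "and median survival gains)."
    ),
    rating_levels={
        1: "Minimal to low clinically meaningful incremental benefit",
        2: "Moderate clinically meaningful incremental benefit",
        3: "Substantial clinically meaningful incremental benefit",
    },
    measure_kind=MeasureKind.QUANTITATIVE_RULE,
)

_MAGNITUDE = Criterion(
    id="magnitude_of_uncertainty",
    name="Magnitude of uncertainty",
    group=Group.A_IMPORTANCE,
    description=(
        "Degree of the uncertainty identified during funding deliberations "
        "(effectiveness, toxicity, quality of life, costs...); quantitatively "
        "conceptualized as the percent variation in survival confidence "
        "intervals or in the assessed ICER range."
    ),
    rating_levels={
        1: "Minimal uncertainty (<10% variation)",
        2: "Moderate uncertainty (10-25% variation)",
        3: "Substantial uncertainty (>25% variation)",
    },
    measure_kind=MeasureKind.QUANTITATIVE_RULE,
)

_IMPACT = Criterion(
    id="impact_of_uncertainty",
    name="Impact of uncertainty",
    group=Group.A_IMPORTANCE,
    description=(
        "Potential impact of the uncertainty on total incremental benefits "
        "and/or costs versus the relevant comparator. Removed from the final "
        "instrument as redundant with relevance of uncertainty."
    ),
    rating_levels={1: "Low impact", 2: "Moderate impact", 3: "Substantial impact"},
    measure_kind=MeasureKind.QUALITATIVE_EXPERT,
)

_RELEVANCE = Criterion(
    id="relevance_of_uncertainty",
    name="Relevance of uncertainty",
    group=Group.A_IMPORTANCE,
    description=(
        "Likelihood, as judged by experts, that resolving the uncertainty "
        "would change funding status (e.g. price re-negotiation) or clinical "
        "treatment recommendations."
    ),
    rating_levels={
        1: "Indirect relevance",
        2: "Moderate relevance",
        3: "Substantial relevance",
    },
    measure_kind=MeasureKind.QUALITATIVE_EXPERT,
)

_COMPARATOR = Criterion(
    id="comparator",
    name="Comparator",
    group=Group.B_FEASIBILITY,
    description=(
        "Likelihood that a relevant comparator population of sufficient size "
        "(treated per current standard of care) can be identified within a "
        "reasonable time frame."
    ),
    rating_levels=_CONCERN_LEVELS,
    measure_kind=MeasureKind.SEMI_QUANTITATIVE_CHECKLIST,
)

_CASES = Criterion(
    id="cases",
    name="Cases",
    group=Group.B_FEASIBILITY,
    description=(
        "Likelihood of accruing a sufficient treated sample, with follow-up "
        "for the relevant outcomes, within a reasonable time (less than half "
        "the remaining patent life)."
    ),
    rating_levels=_CONCERN_LEVELS,
    measure_kind=MeasureKind.SEMI_QUANTITATIVE_CHECKLIST,
)

_DATA = Criterion(
    id="data",
    name="Data",
    group=Group.B_FEASIBILITY,
    description=(
        "Availability and completeness of high-quality real-world data for "
        "exposed and comparator cohorts: eligibility-defining "
        "characteristics, covariates, and line-of-therapy identification."
    ),
    rating_levels=_CONCERN_LEVELS,
    measure_kind=MeasureKind.SEMI_QUANTITATIVE_CHECKLIST,
)

_EXPERTISE_METHODOLOGY = Criterion(
    id="expertise_and_methodology",
    name="Expertise and methodology",
    group=Group.B_FEASIBILITY,
    description=(
        "Availability of the required expertise (clinical, analytic, "
        "methodological) and of suitable methods to conduct the study."
    ),
    rating_levels=_CONCERN_LEVELS,
    measure_kind=MeasureKind.SEMI_QUANTITATIVE_CHECKLIST,
)

_EXPERTISE = Criterion(
    id="expertise",
    name="Expertise",
    group=Group.B_FEASIBILITY,
    description="Availability of expertise to conduct the RWE analysis.",
    rating_levels=_CONCERN_LEVELS,
    measure_kind=MeasureKind.SEMI_QUANTITATIVE_CHECKLIST,
)

_METHODOLOGY = Criterion(
    id="methodology",
    name="Methodology",
    group=Group.B_FEASIBILITY,
    description=(
        "Availability of appropriate methodology, given current data "
        "availability and the clinical context."
    ),
    rating_levels=_CONCERN_LEVELS,
    measure_kind=MeasureKind.SEMI_QUANTITATIVE_CHECKLIST,
)

_TIME = Criterion(
    id="time",
    name="Time",
    group=Group.B_FEASIBILITY,
    description=(
        "Approximate reconstruction of the draft 'Time' criterion, later "
        "folded into the sample-size and comparator criteria as the "
        "reasonable-time-frame condition."
    ),
    rating_levels=_CONCERN_LEVELS,
    measure_kind=MeasureKind.QUALITATIVE_EXPERT,
)

#: Published weights of the final 7-criterion instrument (percent).
FINAL_WEIGHTS: dict[str, float] = {
    "benefit": 17.65,
    "magnitude_of_uncertainty": 10.6,
    "relevance_of_uncertainty": 18.8,
    "comparator": 11.8,
    "cases": 14.1,
    "data": 17.65,
    "expertise_and_methodology": 9.4,
}


def default_criterion_set() -> CriterionSet:
    """The final 7-criterion set with its published weights (tag ``v2_final7``)."""
    return CriterionSet(
        version_tag="v2_final7",
        criteria=(
            _BENEFIT,
            _MAGNITUDE,
            _RELEVANCE,
            _COMPARATOR,
            _CASES,
            _DATA,
            _EXPERTISE_METHODOLOGY,
        ),
        weights=dict(FINAL_WEIGHTS),
    )


def _equal_weights(criteria: tuple[Criterion, ...]) -> dict[str, float]:
    base = TOTAL_WEIGHT / len(criteria)
    return {c.id: base for c in criteria}


def table1_criterion_set() -> CriterionSet:
    """The 9-criterion intermediate set (tag ``v1_table1_9``), equal weights."""
    criteria = (
        _BENEFIT,
        _MAGNITUDE,
        _IMPACT,
        _RELEVANCE,
        _COMPARATOR,
        _CASES.model_copy(update={"name": "Sample size"}),
        _DATA,
        _EXPERTISE,
        _METHODOLOGY,
    )
    return CriterionSet(
        version_tag="v1_table1_9",
        criteria=criteria,
        weights=_equal_weights(criteria),
    )


def draft_criterion_set() -> CriterionSet:
    """The 10-criterion draft set (tag ``v0_draft10``), equal weights.

    Reconstructed by name only; the draft's verbatim content was not
    published, so descriptions are approximate.
    """
    v1 = table1_criterion_set()
    criteria = v1.criteria + (_TIME,)
    return CriterionSet(
        version_tag="v0_draft10",
        criteria=criteria,
        weights=_equal_weights(criteria),
    )


BUILTIN_SETS = {
    "v2_final7": default_criterion_set,
    "v1_table1_9": table1_criterion_set,
    "v0_draft10": draft_criterion_set,
}


# ---------------------------------------------------------------------------
# structural operations
# ---------------------------------------------------------------------------

def remove_criterion(
    cset: CriterionSet,
    criterion_id: str,
    mode: str = "proportional_renormalize",
) -> CriterionSet:
    """Remove a criterion, rescaling the survivors back to a 100 total.

    Each remaining weight is multiplied by ``100 / (100 - removed_weight)``,
    so relative proportions among the survivors are preserved.  The input set
    is not modified.
    """
    if mode != "proportional_renormalize":
        raise CriterionSetError(f"unknown removal mode: {mode!r}")
    if criterion_id not in cset.weights:
        raise CriterionSetError(f"criterion not found: {criterion_id!r}")
    if len(cset.criteria) < 2:
        raise CriterionSetError("cannot empty criterion set")
    removed = cset.weights[criterion_id]
    factor = TOTAL_WEIGHT / (TOTAL_WEIGHT - removed)
    criteria = tuple(c for c in cset.criteria if c.id != criterion_id)
    weights = {c.id: cset.weights[c.id] * factor for c in criteria}
    return CriterionSet(
        version_tag=f"{cset.version_tag}-remove_{criterion_id}",
        criteria=criteria,
        weights=weights,
    )


def merge_criteria(
    cset: CriterionSet,
    ids: tuple[str, str],
    new_id: str,
    new_name: str,
    rating_levels: Optional[dict[int, str]] = None,
    description: Optional[str] = None,
) -> CriterionSet:
    """Merge two same-group criteria into one carrying their pooled weight.

    The merged criterion takes the position of the first id; its default
    weight is the exact sum of the pair's weights, so no renormalization is
    needed and all other weights are untouched.  ``rating_levels`` defaults
    to the first member's descriptors.
    """
    id_a, id_b = ids
    if id_a == id_b:
        raise CriterionSetError("cannot merge a criterion with itself")
    crit_a = cset.criterion(id_a)
    crit_b = cset.criterion(id_b)
    if crit_a.group is not crit_b.group:
        raise CriterionSetError("cross-group merge not allowed")
    surviving = set(cset.ids()) - {id_a, id_b}
    if new_id in surviving:
        raise CriterionSetError(f"id collision: {new_id!r}")

    merged = Criterion(
        id=new_id,
        name=new_name,
        group=crit_a.group,
        description=description
        if description is not None
        else " ".join(d for d in (crit_a.description, crit_b.description) if d),
        rating_levels=rating_levels
        if rating_levels is not None
        else dict(crit_a.rating_levels),
        measure_kind=crit_a.measure_kind,
    )
    criteria = tuple(
        merged if c.id == id_a else c for c in cset.criteria if c.id != id_b
    )
    weights = {c.id: cset.weights[c.id] for c in criteria if c.id != new_id}
    weights[new_id] = cset.weights[id_a] + cset.weights[id_b]
    return CriterionSet(
        version_tag=f"{cset.version_tag}-merge_{new_id}",
        criteria=criteria,
        weights=weights,
    )
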