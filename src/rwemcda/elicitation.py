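"""Survey-driven weight elicitation: equal start, then vote-based adjustment.

The weighting workflow mirrors how the instrument's weights were developed:
each stakeholder names the three criteria they consider most important and
the three they consider least important (but still relevant); organizations
with several members contribute one response; every criterion starts from an
equal weight (10 % each for ten criteria) which is then nudged up or down by
the vote balance; the group may apply final manual adjustments after
discussion.

The adjustment rule here is the simplest monotone one consistent with that
workflow: with net votes ``net_i = most_i - least_i``,

    adjusted_i = base * (1 + alpha * net_i / max(1, max_j |net_j|))

renormalized to sum to 100.  ``alpha`` (default 0.5) sets how strongly the
survey moves weights away from the equal start; the facilitator's actual
adjustment magnitudes were never published, so this rule does not claim to
reproduce the shipped final weights — those remain constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .criteria import TOTAL_WEIGHT, CriterionSet
from .errors import McdaError

DEFAULT_ALPHA = 0.5
# Guards the positivity of derived weights at the alpha=1 extreme, where the
# linear rule would otherwise hit exactly zero.
_POSITIVITY_FLOOR = 1e-12


class SurveyResponse(BaseModel):
    """One stakeholder's most/least-important votes (three of each, disjoint)."""

    model_config = ConfigDict(frozen=True)

    respondent_id: str
    organization: Optional[str] = None
    most_important: tuple[str, str, str]
    least_important: tuple[str, str, str]

    @model_validator(mode="after")
    def _check(self) -> "SurveyResponse":
        most, least = set(self.most_important), set(self.least_important)
        if len(most) != 3 or len(least) != 3:
            raise ValueError("most/least important must each name three distinct criteria")
        if most & least:
            raise ValueError(
                "most_important and least_important must be disjoint"
            )
        return self


@dataclass(frozen=True)
class VoteTally:
    """Vote counts per criterion over the retained responses."""

    most_votes: Mapping[str, int]
    least_votes: Mapping[str, int]
    n_responses: int

    @property
    def net(self) -> dict[str, int]:
        return {
            cid: self.most_votes[cid] - self.least_votes[cid]
            for cid in self.most_votes
        }


def dedupe_by_organization(
    responses: Iterable[SurveyResponse],
) -> list[SurveyResponse]:
    """Keep at most one response per organization.

    Among duplicates the response with the smallest respondent id is kept;
    responses without an organization are all retained.  Input order is
    preserved in the output.
    """
    responses = list(responses)
    keeper: dict[str, str] = {}
    for r in responses:
        if r.organization:
            if (
                r.organization not in keeper
                or r.respondent_id < keeper[r.organization]
            ):
                keeper[r.organization] = r.respondent_id
    return [
        r
        for r in responses
        if not r.organization or keeper[r.organization] == r.respondent_id
    ]


def tally(
    responses: Iterable[SurveyResponse], cset: CriterionSet
) -> VoteTally:
    """Count most/least votes per criterion; unvoted criteria get zeros."""
    most = {cid: 0 for cid in cset.ids()}
    least = {cid: 0 for cid in cset.ids()}
    n = 0
    for r in responses:
        n += 1
        for cid in r.most_important:
            if cid not in most:
                raise McdaError(f"unknown criterion in survey: {cid!r}")
            most[cid] += 1
        for cid in r.least_important:
            if cid not in least:
                raise McdaError(f"unknown criterion in survey: {cid!r}")
            least[cid] += 1
    return VoteTally(most_votes=most, least_votes=least, n_responses=n)


def derive_weights(
    vote_tally: VoteTally,
    cset: CriterionSet,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, float]:
    """Equal-start weights adjusted by net votes, renormalized to 100.

    With no votes at all this is the exact equal split (10.0 each for ten
    criteria).  For fixed ``alpha``, a criterion with a strictly larger net
    vote always receives a strictly larger weight.
    """
    if not 0 < alpha <= 1:
        raise McdaError("alpha must be in (0, 1]")
    ids = cset.ids()
    if not ids:
        raise McdaError("empty criterion set")
    net = vote_tally.net
    missing = set(ids) - set(net)
    if missing:
        raise McdaError(f"tally missing criteria: {sorted(missing)}")
    base = TOTAL_WEIGHT / len(ids)
    scale = max(1, max(abs(v) for v in net.values()))
    adjusted = {
        cid: max(base * (1 + alpha * net[cid] / scale), base * _POSITIVITY_FLOOR)
        for cid in ids
    }
    total = sum(adjusted.values())
    return {cid: adjusted[cid] * TOTAL_WEIGHT / total for cid in ids}


def apply_manual_adjustments(
    weights: Mapping[str, float],
    deltas: Mapping[str, float],
) -> dict[str, float]:
    """Add per-criterion deltas, then renormalize back to a 100 total."""
    unknown = set(deltas) - set(weights)
    if unknown:
        raise McdaError(f"unknown criteria in adjustments: {sorted(unknown)}")
    shifted = {
        cid: w + deltas.get(cid, 0.0) for cid, w in weights.items()
    }
    if any(w <= 0 for w in shifted.values()):
        raise McdaError("weight must remain positive")
    total = sum(shifted.values())
    return {cid: w * TOTAL_WEIGHT / total for cid, w in shifted.items()}
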