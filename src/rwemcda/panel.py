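"""Multi-rater panel sessions: discordance flags, consensus, agreement.

In the piloted workflow several raters score a proposal independently, the
facilitator flags criteria where ratings diverge, and the panel resolves
divergence through discussion — consensus is *recorded*, never computed, so
this module deliberately refuses to average ratings across raters.

On a 3-point scale the per-criterion spread (max - min) is exhaustive:
0 -> no discordance, 1 -> worth discussing, 2 -> severe (opposite ends of
the scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .criteria import RatingVector
from .errors import PanelError


class DiscordanceLevel(str, Enum):
    NONE = "none"
    DISCUSS = "discuss"
    SEVERE = "severe"


_LEVEL_BY_RANGE = {
    0: DiscordanceLevel.NONE,
    1: DiscordanceLevel.DISCUSS,
    2: DiscordanceLevel.SEVERE,
}


class DiscussionNote(BaseModel):
    model_config = ConfigDict(frozen=True)

    criterion_id: str
    note: str


class PanelSession(BaseModel):
    """One proposal rated independently by a panel of raters."""

    model_config = ConfigDict(frozen=True)

    session_id: str
    proposal_id: str
    criterion_set_version: str
    rater_vectors: dict[str, RatingVector]
    consensus: Optional[RatingVector] = None
    discussion_log: tuple[DiscussionNote, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "PanelSession":
        if not self.rater_vectors:
            raise ValueError("a session needs at least one rater")
        key_sets = {frozenset(rv.ratings) for rv in self.rater_vectors.values()}
        if len(key_sets) != 1:
            raise ValueError("all rater vectors must cover the same criteria")
        for rv in self.rater_vectors.values():
            if rv.proposal_id != self.proposal_id:
                raise ValueError(
                    "rater vectors must be for the session's proposal"
                )
        if self.consensus is not None:
            if set(self.consensus.ratings) != set(self.criterion_ids()):
                raise ValueError("consensus must cover all criteria")
        return self

    def criterion_ids(self) -> frozenset[str]:
        return frozenset(next(iter(self.rater_vectors.values())).ratings)


def discordance(session: PanelSession) -> dict[str, DiscordanceLevel]:
    """Per-criterion discordance from the spread of rater ratings."""
    if len(session.rater_vectors) < 2:
        raise PanelError("discordance undefined for one rater")
    out: dict[str, DiscordanceLevel] = {}
    for cid in sorted(session.criterion_ids()):
        values = [rv.ratings[cid] for rv in session.rater_vectors.values()]
        out[cid] = _LEVEL_BY_RANGE[max(values) - min(values)]
    return out


def record_consensus(
    session: PanelSession,
    consensus: RatingVector,
    notes: Optional[Mapping[str, str]] = None,
) -> PanelSession:
    """Attach a consensus vector, insisting on documentation of surprises.

    Wherever the consensus rating differs from *every* individual rating on
    that criterion, a discussion note for that criterion is required (either
    already in the session log or supplied via ``notes``) so the departure
    is explained on the record.
    """
    if set(consensus.ratings) != set(session.criterion_ids()):
        raise PanelError("consensus does not match the session's criterion set")
    if consensus.proposal_id != session.proposal_id:
        raise PanelError("consensus is for a different proposal")
    notes = dict(notes or {})
    noted = {n.criterion_id for n in session.discussion_log} | set(notes)
    for cid in session.criterion_ids():
        individual = {rv.ratings[cid] for rv in session.rater_vectors.values()}
        if consensus.ratings[cid] not in individual and cid not in noted:
            raise PanelError(
                f"unexplained consensus deviation on {cid!r}: consensus "
                f"{consensus.ratings[cid]} matches no individual rating"
            )
    log = session.discussion_log + tuple(
        DiscussionNote(criterion_id=cid, note=text)
        for cid, text in sorted(notes.items())
    )
    return session.model_copy(update={"consensus": consensus, "discussion_log": log})


@dataclass(frozen=True)
class AgreementSummary:
    """Share of sessions with unanimous ratings, per criterion and overall."""

    per_criterion: Mapping[str, float]
    overall_mean: float


def agreement_summary(sessions: Iterable[PanelSession]) -> AgreementSummary:
    """Exact-agreement proportion per criterion across sessions."""
    sessions = list(sessions)
    if not sessions:
        raise PanelError("no sessions")
    for s in sessions:
        if len(s.rater_vectors) < 2:
            raise PanelError("agreement undefined for single-rater sessions")
    cids = sessions[0].criterion_ids()
    for s in sessions[1:]:
        if s.criterion_ids() != cids:
            raise PanelError("sessions use different criterion sets")
    per: dict[str, float] = {}
    for cid in sorted(cids):
        unanimous = sum(
            1
            for s in sessions
            if len({rv.ratings[cid] for rv in s.rater_vectors.values()}) == 1
        )
        per[cid] = unanimous / len(sessions)
    return AgreementSummary(
        per_criterion=per, overall_mean=sum(per.values()) / len(per)
    )
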