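"""Additive aggregation, portfolio ranking, and rank-stability analysis.

The aggregate score of a proposal is the weighted sum of its seven criterion
ratings, ``total = sum_i w_i * r_i``, with weights in percent (summing to
100) and ratings on the 3-point scale — so totals live on a 100-300 scale.
Group subtotals (importance vs. feasibility) partition the total.  Ranking
is descending by total; exact ties are flagged rather than resolved, since
equal scores are meant to go back to deliberation.

Because consensus-derived weights are imprecise, :func:`rank_stability`
perturbs them with a Dirichlet distribution centred on the nominal weights
and reports how often each proposal keeps its nominal rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .criteria import CriterionSet, Group, RatingVector
from .errors import McdaError

#: Totals within this absolute distance are treated as tied.
TIE_TOL = 1e-9


@dataclass(frozen=True)
class AggregateScore:
    """Weighted additive score for one proposal, with its decomposition."""

    proposal_id: str
    total: float
    group_a_subtotal: float
    group_b_subtotal: float
    per_criterion_contribution: Mapping[str, float]


@dataclass(frozen=True)
class RankRow:
    proposal_id: str
    total: float
    group_a_subtotal: float
    group_b_subtotal: float
    rank: int
    tied: bool


@dataclass(frozen=True)
class RankTable:
    """Proposals in priority order (rank 1 = best; ties share the smaller rank)."""

    rows: tuple[RankRow, ...]

    def rank_of(self, proposal_id: str) -> int:
        for row in self.rows:
            if row.proposal_id == proposal_id:
                return row.rank
        raise McdaError(f"unknown proposal: {proposal_id!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "proposal_id": r.proposal_id,
                    "total": r.total,
                    "group_a": r.group_a_subtotal,
                    "group_b": r.group_b_subtotal,
                    "rank": r.rank,
                    "tied": r.tied,
                }
                for r in self.rows
            ]
        )


def aggregate(rv: RatingVector, cset: CriterionSet) -> AggregateScore:
    """Weighted additive aggregate of one rating vector under ``cset``."""
    if not rv.bound_to(cset):
        raise McdaError(
            "rating/criterion-set mismatch: ratings cover "
            f"{sorted(rv.ratings)} but set has {sorted(cset.ids())}"
        )
    contributions = {
        cid: cset.weights[cid] * rv.ratings[cid] for cid in cset.ids()
    }
    group_a = sum(
        contributions[cid] for cid in cset.ids_in_group(Group.A_IMPORTANCE)
    )
    group_b = sum(
        contributions[cid] for cid in cset.ids_in_group(Group.B_FEASIBILITY)
    )
    return AggregateScore(
        proposal_id=rv.proposal_id,
        total=sum(contributions.values()),
        group_a_subtotal=group_a,
        group_b_subtotal=group_b,
        per_criterion_contribution=contributions,
    )


def _competition_ranks(
    totals: Sequence[float],
) -> tuple[list[int], list[bool]]:
    """Ranks for totals already sorted descending; ties share the smaller rank."""
    n = len(totals)
    ranks = [0] * n
    tied = [False] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and abs(totals[j + 1] - totals[i]) <= TIE_TOL:
            j += 1
        for k in range(i, j + 1):
            ranks[k] = i + 1
            tied[k] = j > i
        i = j + 1
    return ranks, tied


def rank_portfolio(scores: Iterable[AggregateScore]) -> RankTable:
    """Order proposals by descending total.

    Near-equal totals (within ``TIE_TOL``) share the smaller rank and are
    flagged as tied.  The display order among tied proposals (higher Group A
    subtotal first, then proposal id) is a stable convention only — the tie
    flag is what tells humans to deliberate.
    """
    scores = list(scores)
    if not scores:
        raise McdaError("no scores to rank")
    ids = [s.proposal_id for s in scores]
    if len(set(ids)) != len(ids):
        raise McdaError("duplicate proposal id")
    ordered = sorted(
        scores,
        key=lambda s: (-s.total, -s.group_a_subtotal, s.proposal_id),
    )
    ranks, tied = _competition_ranks([s.total for s in ordered])
    rows = tuple(
        RankRow(
            proposal_id=s.proposal_id,
            total=s.total,
            group_a_subtotal=s.group_a_subtotal,
            group_b_subtotal=s.group_b_subtotal,
            rank=rank,
            tied=t,
        )
        for s, rank, t in zip(ordered, ranks, tied)
    )
    return RankTable(rows=rows)


def _ranks_for_weights(
    ratings: np.ndarray,
    ratings_a: np.ndarray,
    ids: Sequence[str],
    weights: np.ndarray,
    weights_a: np.ndarray,
) -> dict[str, int]:
    """Rank map for one weight vector, matching rank_portfolio's semantics."""
    totals = ratings @ weights
    group_a = ratings_a @ weights_a
    order = sorted(
        range(len(ids)), key=lambda i: (-totals[i], -group_a[i], ids[i])
    )
    ranks, _ = _competition_ranks([totals[i] for i in order])
    return {ids[i]: rank for i, rank in zip(order, ranks)}


def rank_stability(
    rating_vectors: Iterable[RatingVector],
    cset: CriterionSet,
    concentration: float = 100.0,
    n_draws: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Probability each proposal retains its nominal rank under weight noise.

    Weights are redrawn from ``Dirichlet(concentration * w / 100)`` — mean
    equal to the nominal weights, spread shrinking as ``concentration``
    grows; ``concentration=math.inf`` disables the perturbation entirely
    (every retention probability is then 1).  Deterministic given ``seed``.
    """
    if not concentration > 0:
        raise McdaError("invalid concentration")
    if n_draws < 1:
        raise McdaError("n_draws must be >= 1")
    vectors = list(rating_vectors)
    if not vectors:
        raise McdaError("no rating vectors")
    for rv in vectors:
        if not rv.bound_to(cset):
            raise McdaError(
                f"rating/criterion-set mismatch for {rv.proposal_id!r}"
            )
    ids = [rv.proposal_id for rv in vectors]
    cids = list(cset.ids())
    a_mask = np.array(
        [cset.group_of(cid) is Group.A_IMPORTANCE for cid in cids]
    )
    ratings = np.array(
        [[rv.ratings[cid] for cid in cids] for rv in vectors], dtype=float
    )
    ratings_a = ratings[:, a_mask]
    w0 = np.array([cset.weights[cid] for cid in cids], dtype=float)

    nominal = _ranks_for_weights(ratings, ratings_a, ids, w0, w0[a_mask])
    retained = {pid: 0 for pid in ids}
    rng = np.random.default_rng(seed)
    for _ in range(n_draws):
        if math.isinf(concentration):
            w = w0
        else:
            w = rng.dirichlet(concentration * w0 / w0.sum()) * w0.sum()
        draw_ranks = _ranks_for_weights(ratings, ratings_a, ids, w, w[a_mask])
        for pid in ids:
            if draw_ranks[pid] == nominal[pid]:
                retained[pid] += 1
    return {pid: retained[pid] / n_draws for pid in ids}


def normalized_total(score: AggregateScore) -> float:
    """Total rescaled from the raw 100-300 scale to [1/3, 1] (divide by 300)."""
    return score.total / 300.0
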