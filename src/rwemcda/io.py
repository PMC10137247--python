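"""File formats: YAML/JSON proposals and criterion sets, CSV sheets, reports.

Conventions: UTF-8 throughout; months and years as floats; ICERs as plain
numbers (currency-agnostic); criterion sets and evidence profiles in YAML or
JSON (chosen by file extension); surveys, panel sheets, rating vectors and
rank tables as CSV.  Validation is pydantic-backed — a malformed record
raises :class:`~rwemcda.errors.SchemaError` naming the field and record.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .criteria import (
    BUILTIN_SETS,
    CriterionSet,
    Provenance,
    RatingVector,
    default_criterion_set,
)
from .elicitation import SurveyResponse
from .errors import SchemaError
from .evidence import EvidenceProfile
from .panel import DiscordanceLevel, PanelSession, discordance
from .scoring import AggregateScore, RankTable

PathLike = Union[str, Path]

#: rater_id marking a consensus row in a panel sheet.
CONSENSUS_RATER = "CONSENSUS"


def _format_validation_error(record: str, err: ValidationError) -> SchemaError:
    first = err.errors()[0]
    field = ".".join(str(p) for p in first["loc"]) or "<root>"
    return SchemaError(f"{record}: field {field!r}: {first['msg']}")


def _load_structured(path: PathLike) -> object:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _dump_structured(data: object, path: PathLike) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(
            yaml.safe_dump(data, sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )


# -- criterion sets ---------------------------------------------------------

def load_criterion_set(ref: str) -> CriterionSet:
    """Load a set from ``builtin:<tag>`` or a YAML/JSON file path."""
    if ref.startswith("builtin:"):
        tag = ref.removeprefix("builtin:")
        if tag not in BUILTIN_SETS:
            raise SchemaError(
                f"unknown builtin criterion set {tag!r}; "
                f"choose from {sorted(BUILTIN_SETS)}"
            )
        return BUILTIN_SETS[tag]()
    try:
        return CriterionSet.from_dict(_load_structured(ref))
    except ValidationError as err:
        raise _format_validation_error(f"criterion set {ref}", err) from err


def write_criterion_set(cset: CriterionSet, path: PathLike) -> None:
    _dump_structured(cset.to_dict(), path)


# -- evidence profiles ------------------------------------------------------

def profile_schema() -> dict:
    """JSON Schema for one evidence profile (for external validators)."""
    return EvidenceProfile.model_json_schema()


def read_profiles(path: PathLike) -> list[EvidenceProfile]:
    """Read one profile or a list of profiles from YAML/JSON."""
    data = _load_structured(path)
    if isinstance(data, dict) and "profiles" in data:
        data = data["profiles"]
    if isinstance(data, dict):
        data = [data]
    if not isinstance(data, list):
        raise SchemaError(f"{path}: expected a profile or list of profiles")
    profiles = []
    for i, record in enumerate(data):
        try:
            profiles.append(EvidenceProfile.model_validate(record))
        except ValidationError as err:
            pid = record.get("proposal_id", f"record {i}") if isinstance(record, dict) else f"record {i}"
            raise _format_validation_error(f"profile {pid}", err) from err
    return profiles


def write_profiles(
    profiles: Sequence[EvidenceProfile],
    path: PathLike,
    seed: Optional[int] = None,
) -> None:
    """Write profiles; a generation seed, when given, is recorded in the file."""
    payload: dict = {"profiles": [p.model_dump(mode="json") for p in profiles]}
    if seed is not None:
        payload["generator_seed"] = seed
    _dump_structured(payload, path)


# -- rating vectors ---------------------------------------------------------

def write_ratings_csv(
    vectors: Sequence[RatingVector],
    cset: CriterionSet,
    path_or_buf: Union[PathLike, TextIO],
) -> None:
    rows = []
    for rv in vectors:
        row: dict = {"proposal_id": rv.proposal_id, "rater_id": rv.rater_id or ""}
        for cid in cset.ids():
            row[cid] = rv.ratings[cid]
            row[f"{cid}__provenance"] = rv.provenance[cid].value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)


def read_ratings_csv(
    path: PathLike, cset: CriterionSet
) -> list[RatingVector]:
    df = pd.read_csv(path, dtype={"proposal_id": str})
    missing = [cid for cid in cset.ids() if cid not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing criterion columns {missing}")
    vectors = []
    for _, row in df.iterrows():
        pid = str(row["proposal_id"])
        ratings, prov = {}, {}
        for cid in cset.ids():
            value = row[cid]
            try:
                ratings[cid] = int(value)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"ratings for {pid}: field {cid!r}: not an integer rating"
                )
            prov_col = f"{cid}__provenance"
            prov[cid] = (
                Provenance(row[prov_col])
                if prov_col in df.columns and pd.notna(row[prov_col])
                else Provenance.EXPERT_ASSERTED
            )
        rater = row.get("rater_id")
        try:
            vectors.append(
                RatingVector(
                    proposal_id=pid,
                    ratings=ratings,
                    provenance=prov,
                    rater_id=None if pd.isna(rater) or rater == "" else str(rater),
                )
            )
        except ValidationError as err:
            raise _format_validation_error(f"ratings for {pid}", err) from err
    return vectors


# -- surveys ----------------------------------------------------------------

def read_survey_csv(path: PathLike) -> list[SurveyResponse]:
    """Survey CSV: respondent_id, organization, most1..most3, least1..least3."""
    df = pd.read_csv(path, dtype=str)
    needed = ["respondent_id", "most1", "most2", "most3", "least1", "least2", "least3"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing survey columns {missing}")
    responses = []
    for _, row in df.iterrows():
        org = row.get("organization")
        try:
            responses.append(
                SurveyResponse(
                    respondent_id=str(row["respondent_id"]),
                    organization=None if pd.isna(org) or org == "" else str(org),
                    most_important=(row["most1"], row["most2"], row["most3"]),
                    least_important=(row["least1"], row["least2"], row["least3"]),
                )
            )
        except ValidationError as err:
            raise _format_validation_error(
                f"survey response {row['respondent_id']}", err
            ) from err
    return responses


def write_weights_yaml(weights: dict[str, float], path: PathLike) -> None:
    """Weights fragment loadable back into a criterion-set file."""
    Path(path).write_text(
        yaml.safe_dump({"weights": weights}, sort_keys=False), encoding="utf-8"
    )


# -- panel sheets -----------------------------------------------------------

def write_panel_csv(
    sessions: Sequence[PanelSession],
    cset: CriterionSet,
    path_or_buf: Union[PathLike, TextIO],
) -> None:
    rows = []
    for s in sessions:
        for rid in sorted(s.rater_vectors):
            rv = s.rater_vectors[rid]
            row = {"session_id": s.session_id, "proposal_id": s.proposal_id,
                   "rater_id": rid}
            row.update({cid: rv.ratings[cid] for cid in cset.ids()})
            rows.append(row)
        if s.consensus is not None:
            row = {"session_id": s.session_id, "proposal_id": s.proposal_id,
                   "rater_id": CONSENSUS_RATER}
            row.update({cid: s.consensus.ratings[cid] for cid in cset.ids()})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)


def read_panel_csv(path: PathLike, cset: CriterionSet) -> list[PanelSession]:
    df = pd.read_csv(path, dtype={"session_id": str, "proposal_id": str, "rater_id": str})
    needed = ["session_id", "proposal_id", "rater_id"]
    missing = [c for c in needed if c not in df.columns] + [
        cid for cid in cset.ids() if cid not in df.columns
    ]
    if missing:
        raise SchemaError(f"{path}: missing panel-sheet columns {missing}")
    sessions = []
    for sid, group in df.groupby("session_id", sort=False):
        pids = group["proposal_id"].unique()
        if len(pids) != 1:
            raise SchemaError(
                f"panel session {sid}: multiple proposal ids {list(pids)}"
            )
        pid = str(pids[0])

        def vector(row, rater_id) -> RatingVector:
            ratings = {}
            for cid in cset.ids():
                try:
                    ratings[cid] = int(row[cid])
                except (TypeError, ValueError):
                    raise SchemaError(
                        f"panel session {sid}, rater {rater_id}: field "
                        f"{cid!r}: not an integer rating"
                    )
            try:
                return RatingVector.from_ratings(pid, ratings, rater_id=rater_id)
            except ValidationError as err:
                raise _format_validation_error(
                    f"panel session {sid}, rater {rater_id}", err
                ) from err

        raters, consensus = {}, None
        for _, row in group.iterrows():
            rid = str(row["rater_id"])
            if rid == CONSENSUS_RATER:
                consensus = vector(row, None)
            else:
                raters[rid] = vector(row, rid)
        try:
            sessions.append(
                PanelSession(
                    session_id=str(sid),
                    proposal_id=pid,
                    criterion_set_version=cset.version_tag,
                    rater_vectors=raters,
                    consensus=consensus,
                )
            )
        except ValidationError as err:
            raise _format_validation_error(f"panel session {sid}", err) from err
    return sessions


# -- rank tables and reports ------------------------------------------------

def write_rank_table_csv(
    table: RankTable, path_or_buf: Union[PathLike, TextIO]
) -> None:
    table.to_frame().to_csv(path_or_buf, index=False)


def render_report(
    scores: Sequence[AggregateScore],
    table: RankTable,
    sessions: Sequence[PanelSession] = (),
    normalize: bool = False,
) -> str:
    """Human-readable prioritization report.

    Shows the rank table, each proposal's per-criterion contributions, and —
    when panel sessions are supplied — the discordance flags that should
    drive the discussion.
    """
    by_id = {s.proposal_id: s for s in scores}
    lines = ["Prioritization report", "=" * 21, "", "Rank table:"]
    for row in table.rows:
        total = row.total / 300.0 if normalize else row.total
        tied = "  (tied)" if row.tied else ""
        lines.append(
            f"  {row.rank:>3}. {row.proposal_id}  total={total:.4g}  "
            f"importance={row.group_a_subtotal:.4g}  "
            f"feasibility={row.group_b_subtotal:.4g}{tied}"
        )
    lines.append("")
    lines.append("Per-criterion contributions (weight x rating):")
    for row in table.rows:
        score = by_id[row.proposal_id]
        parts = ", ".join(
            f"{cid}={v:.4g}"
            for cid, v in score.per_criterion_contribution.items()
        )
        lines.append(f"  {row.proposal_id}: {parts}")
    if sessions:
        lines.append("")
        lines.append("Panel discordance (per criterion):")
        for s in sessions:
            flags = discordance(s)
            flagged = {
                cid: lvl.value
                for cid, lvl in flags.items()
                if lvl is not DiscordanceLevel.NONE
            }
            lines.append(
                f"  {s.session_id} ({s.proposal_id}): "
                + (", ".join(f"{c}={v}" for c, v in flagged.items()) or "none")
            )
    return "\n".join(lines) + "\n"


def write_report(
    scores: Sequence[AggregateScore],
    table: RankTable,
    path: PathLike,
    sessions: Sequence[PanelSession] = (),
    normalize: bool = False,
) -> None:
    Path(path).write_text(
        render_report(scores, table, sessions, normalize), encoding="utf-8"
    )
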