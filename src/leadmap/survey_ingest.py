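"""Reading, validation and de-identification of roster advice-seeking surveys.

The pipeline consumes two flat UTF-8 CSV tables:

* the **survey table** — one row per respondent, with role, demographics, a
  consent flag, the roster nominations (``target:frequency`` pairs separated
  by semicolons) and eight 5-point Likert self-perception items (two per
  leadership style);
* the **rating table** — one row per preceptor who rated the importance of
  the four leadership styles on a 1-4 scale (1 = most important, ties
  allowed).

Rows without consent and rows with excluded roles are dropped at read time
and counted; self-nominations are removed because a respondent cannot seek
advice from themselves in the adjacency-matrix formulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger("leadmap")

#: The four leadership styles, in canonical order.
STYLES: tuple[str, ...] = ("relational", "transformational", "adaptive", "resilient")

#: Fixed mapping of the eight Likert items (0-based positions) to styles,
#: two consecutive items per style.
ITEM_STYLE_MAP: tuple[str, ...] = (
    "transformational", "transformational",
    "relational", "relational",
    "adaptive", "adaptive",
    "resilient", "resilient",
)

SURVEY_COLUMNS = [
    "actor_id", "role", "gender", "years_doctor_band", "years_specialty_band",
    "consent", "nominations",
] + [f"likert_{i}" for i in range(1, 9)]

RATING_COLUMNS = ["rater_id"] + list(STYLES)


class Role(str, Enum):
    """Included participant categories; rotating residents are excluded."""

    PRECEPTOR = "preceptor"
    R1 = "R1"
    R2 = "R2"
    R3 = "R3"

    @property
    def is_resident(self) -> bool:
        return self is not Role.PRECEPTOR


RESIDENT_ROLES = frozenset({Role.R1, Role.R2, Role.R3})


@dataclass(frozen=True)
class Actor:
    """A network participant: identity, role and descriptive demographics."""

    actor_id: str
    role: Role
    gender: str = "unreported"
    years_doctor_band: str = ""
    years_specialty_band: str = ""


@dataclass(frozen=True)
class NominationRecord:
    """A directed advice-seeking nomination with its survey frequency."""

    source_id: str
    target_id: str
    frequency: int


@dataclass(frozen=True)
class LikertBlock:
    """The self-perception items of one respondent.

    A *complete* block has exactly eight items (two per style); incomplete
    blocks keep the actor in the network analysis but make them ineligible
    for the self-assessment (LAI) score.
    """

    actor_id: str
    item_scores: tuple[int, ...]

    @property
    def complete(self) -> bool:
        return len(self.item_scores) == 8

    def style_means(self) -> dict[str, float]:
        """Mean of the two items mapped to each style; requires a complete block."""
        if not self.complete:
            raise ValidationError(
                f"Likert block of {self.actor_id!r} has {len(self.item_scores)} items; 8 required"
            )
        sums: dict[str, list[int]] = {s: [] for s in STYLES}
        for score, style in zip(self.item_scores, ITEM_STYLE_MAP):
            sums[style].append(score)
        return {s: sum(v) / len(v) for s, v in sums.items()}


@dataclass(frozen=True)
class StyleRating:
    """One preceptor's 1-4 importance rating of each style (1 = most important)."""

    rater_id: str
    ratings: tuple[tuple[str, int], ...]  # ((style, rating), ...) in STYLES order

    def as_dict(self) -> dict[str, int]:
        return dict(self.ratings)


@dataclass
class SurveyDataset:
    """The validated in-memory form of the two survey tables."""

    actors: list[Actor]
    nominations: list[NominationRecord]
    likert: list[LikertBlock]
    ratings: list[StyleRating]
    ingest_log: dict = field(default_factory=dict, compare=False)

    @property
    def actor_ids(self) -> list[str]:
        return [a.actor_id for a in self.actors]

    def roles(self) -> dict[str, Role]:
        return {a.actor_id: a.role for a in self.actors}


@dataclass
class ValidationReport:
    """Structural problems found in a dataset; reporting only, never mutating."""

    duplicate_ids: list[str] = field(default_factory=list)
    dangling_targets: list[str] = field(default_factory=list)
    incomplete_likert: list[str] = field(default_factory=list)
    non_preceptor_raters: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (
            self.duplicate_ids
            or self.dangling_targets
            or self.incomplete_likert
            or self.non_preceptor_raters
        )


def _parse_nominations(cell: str, source_id: str, row_index: int) -> list[NominationRecord]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return []
    records = []
    for part in str(cell).split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            target, freq = part.rsplit(":", 1)
            frequency = int(freq)
        except ValueError as exc:
            raise SchemaError(
                f"row {row_index}: malformed nomination {part!r} (expected 'target:frequency')"
            ) from exc
        if frequency < 0:
            raise ValidationError(f"row {row_index}: negative frequency in {part!r}")
        records.append(NominationRecord(source_id, target.strip(), frequency))
    return records


def _parse_likert(row: pd.Series, row_index: int) -> tuple[int, ...]:
    scores, bad = [], []
    for i in range(1, 9):
        raw = row[f"likert_{i}"]
        if pd.isna(raw) or str(raw).strip() == "":
            continue
        value = int(raw)
        if not 1 <= value <= 5:
            bad.append((row_index, f"likert_{i}", value))
        scores.append(value)
    if bad:
        cells = ", ".join(f"row {r} {c}={v}" for r, c, v in bad)
        raise ValidationError(f"Likert values outside 1..5: {cells}")
    return tuple(scores)


def read_survey(survey_table_path: str | Path, rating_table_path: str | Path) -> SurveyDataset:
    """Read and clean the two survey tables into a :class:`SurveyDataset`.

    Rows with ``consent != "Yes"`` or an excluded role are dropped and
    counted in ``dataset.ingest_log``; self-nominations are removed with a
    logged warning.  Raises :class:`SchemaError` on unknown roles or missing
    columns, :class:`ValidationError` on out-of-range Likert values, and an
    ``OSError`` naming the path if a file cannot be read.
    """
    survey_table_path, rating_table_path = Path(survey_table_path), Path(rating_table_path)
    for p in (survey_table_path, rating_table_path):
        if not p.exists():
            raise FileNotFoundError(f"survey input not readable: {p}")
    survey = pd.read_csv(survey_table_path, dtype=str)
    ratings_tbl = pd.read_csv(rating_table_path, dtype=str)

    missing = [c for c in SURVEY_COLUMNS if c not in survey.columns]
    if missing:
        raise SchemaError(f"survey table missing columns: {missing}")
    missing = [c for c in RATING_COLUMNS if c not in ratings_tbl.columns]
    if missing:
        raise SchemaError(f"rating table missing columns: {missing}")

    actors: list[Actor] = []
    nominations: list[NominationRecord] = []
    likert: list[LikertBlock] = []
    n_rows = len(survey)
    n_dropped_consent = n_dropped_role = n_self_nominations = 0

    for idx, row in survey.iterrows():
        consent = str(row["consent"]).strip()
        if consent != "Yes":
            n_dropped_consent += 1
            continue
        role_raw = str(row["role"]).strip()
        try:
            role = Role(role_raw)
        except ValueError:
            raise SchemaError(f"row {idx}: unknown role value {role_raw!r}") from None
        actor_id = str(row["actor_id"]).strip()
        actors.append(
            Actor(
                actor_id=actor_id,
                role=role,
                gender=str(row["gender"]).strip() if pd.notna(row["gender"]) else "unreported",
                years_doctor_band=str(row["years_doctor_band"]).strip(),
                years_specialty_band=str(row["years_specialty_band"]).strip(),
            )
        )
        for rec in _parse_nominations(row["nominations"], actor_id, idx):
            if rec.target_id == actor_id:
                n_self_nominations += 1
                continue
            nominations.append(rec)
        scores = _parse_likert(row, idx)
        if scores:
            likert.append(LikertBlock(actor_id=actor_id, item_scores=scores))

    ratings: list[StyleRating] = []
    for idx, row in ratings_tbl.iterrows():
        vals = []
        for style in STYLES:
            value = int(row[style])
            if not 1 <= value <= 4:
                raise ValidationError(f"rating row {idx}: {style}={value} outside 1..4")
            vals.append((style, value))
        ratings.append(StyleRating(rater_id=str(row["rater_id"]).strip(), ratings=tuple(vals)))

    if n_dropped_consent:
        logger.warning("dropped %d rows without consent", n_dropped_consent)
    if n_self_nominations:
        logger.warning("removed %d self-nominations", n_self_nominations)

    return SurveyDataset(
        actors=actors,
        nominations=nominations,
        likert=likert,
        ratings=ratings,
        ingest_log={
            "n_rows": n_rows,
            "n_retained": len(actors),
            "n_dropped_consent": n_dropped_consent,
            "n_dropped_role": n_dropped_role,
            "n_self_nominations_removed": n_self_nominations,
        },
    )


def validate_dataset(ds: SurveyDataset) -> ValidationReport:
    """Report structural problems without modifying the dataset."""
    report = ValidationReport()
    seen: set[str] = set()
    for a in ds.actors:
        if a.actor_id in seen:
            report.duplicate_ids.append(a.actor_id)
        seen.add(a.actor_id)
    roster = {a.actor_id for a in ds.actors}
    for rec in ds.nominations:
        if rec.target_id not in roster:
            report.dangling_targets.append(rec.target_id)
    for block in ds.likert:
        if not block.complete:
            report.incomplete_likert.append(block.actor_id)
    preceptors = {a.actor_id for a in ds.actors if a.role is Role.PRECEPTOR}
    for rating in ds.ratings:
        if rating.rater_id not in preceptors:
            report.non_preceptor_raters.append(rating.rater_id)
    if report.incomplete_likert:
        logger.warning(
            "actors with incomplete Likert blocks (LAI-ineligible): %s",
            report.incomplete_likert,
        )
    return report


_ROLE_PREFIX = {Role.PRECEPTOR: "P", Role.R1: "R1.", Role.R2: "R2.", Role.R3: "R3."}
_ROLE_ORDER = {Role.PRECEPTOR: 0, Role.R1: 1, Role.R2: 2, Role.R3: 3}


def deidentify(ds: SurveyDataset) -> tuple[SurveyDataset, dict[str, str]]:
    """Replace actor ids with role-prefixed pseudonyms (P1, R1.1, ...).

    Pseudonyms are assigned after a stable sort by (role, original id), so
    the substitution is deterministic and idempotent in structure; the
    returned ``key_map`` maps pseudonym back to original id.
    """
    ordered = sorted(ds.actors, key=lambda a: (_ROLE_ORDER[a.role], a.actor_id))
    counters: dict[Role, int] = {}
    forward: dict[str, str] = {}
    for a in ordered:
        counters[a.role] = counters.get(a.role, 0) + 1
        forward[a.actor_id] = f"{_ROLE_PREFIX[a.role]}{counters[a.role]}"

    def sub(actor_id: str) -> str:
        return forward.get(actor_id, actor_id)

    new_ds = SurveyDataset(
        actors=[
            Actor(sub(a.actor_id), a.role, a.gender, a.years_doctor_band, a.years_specialty_band)
            for a in ds.actors
        ],
        nominations=[
            NominationRecord(sub(r.source_id), sub(r.target_id), r.frequency)
            for r in ds.nominations
        ],
        likert=[LikertBlock(sub(b.actor_id), b.item_scores) for b in ds.likert],
        ratings=[StyleRating(sub(r.rater_id), r.ratings) for r in ds.ratings],
        ingest_log=dict(ds.ingest_log),
    )
    key_map = {pseudo: orig for orig, pseudo in forward.items()}
    return new_ds, key_map
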