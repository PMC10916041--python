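"""Audit records: field (or synthetic) responses, validation, and I/O.

A :class:`SchoolAudit` is one rater pair's complete walk of one school's
observation route: every audited unit (school access segment, other
segment, crossing) with a response for every item of that unit's section.
Validation is strict and total — malformed input raises
:class:`AuditValidationError` carrying every violation found, and never
yields a partially loaded dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .schema import SECTIONS, ScoringSchema

CSV_COLUMNS = ("school_id", "rater_pair_id", "unit_id", "unit_kind", "item_id", "value")


class AuditValidationError(ValueError):
    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        msg = "; ".join(self.errors[:10])
        if len(self.errors) > 10:
            msg += f"; ... ({len(self.errors)} violations)"
        super().__init__(msg)


@dataclass(frozen=True)
class ItemResponse:
    item_id: str
    value: object


@dataclass(frozen=True)
class UnitAudit:
    unit_id: str
    unit_kind: str  # one of SECTIONS
    responses: tuple  # of ItemResponse, covering the section's item list

    def response_map(self) -> dict:
        return {r.item_id: r.value for r in self.responses}


@dataclass(frozen=True)
class SchoolAudit:
    school_id: str
    rater_pair_id: str
    date: str = ""
    access_segments: tuple = ()
    other_segments: tuple = ()
    crossings: tuple = ()

    def units_for_section(self, section: str) -> tuple:
        return {
            "school_access_segment": self.access_segments,
            "other_segment": self.other_segments,
            "crossing": self.crossings,
        }[section]

    def all_units(self):
        return self.access_segments + self.other_segments + self.crossings


@dataclass
class RatingMatrix:
    """Complete n-subjects x k-raters table of subscale scores."""

    subscale_id: str
    subjects: list
    raters: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if n != len(self.subjects) or k != len(self.raters):
            raise ValueError("values shape does not match subject/rater labels")
        if np.isnan(self.values).any():
            raise ValueError("rating matrix has missing cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# validation


def validate_audit(audit: SchoolAudit, schema: ScoringSchema) -> None:
    """Check one audit against the schema; raise with every violation."""
    errors: list[str] = []
    if not audit.access_segments:
        errors.append(f"school {audit.school_id}: no school access segment audited")
    for section in SECTIONS:
        expected = {it.item_id for it in schema.items_for_section(section)}
        for unit in audit.units_for_section(section):
            where = f"school {audit.school_id} unit {unit.unit_id}"
            if unit.unit_kind != section:
                errors.append(
                    f"{where}: unit_kind {unit.unit_kind!r} in the {section} list"
                )
                continue
            seen: set[str] = set()
            for resp in unit.responses:
                if resp.item_id in seen:
                    errors.append(f"{where}: duplicate response for {resp.item_id}")
                seen.add(resp.item_id)
                if resp.item_id not in expected:
                    errors.append(f"{where}: unknown item_id {resp.item_id!r}")
                    continue
                item = schema.item(resp.item_id)
                if resp.value not in item.response_domain:
                    errors.append(
                        f"{where}: value {resp.value!r} outside the "
                        f"{item.response_domain.kind} domain of {resp.item_id}"
                    )
            missing = expected - seen
            if missing:
                errors.append(
                    f"{where}: missing responses for {sorted(missing)[:5]}"
                    + ("..." if len(missing) > 5 else "")
                )
    if errors:
        raise AuditValidationError(errors)


def validate_audits(audits: Sequence[SchoolAudit], schema: ScoringSchema) -> None:
    errors: list[str] = []
    for audit in audits:
        try:
            validate_audit(audit, schema)
        except AuditValidationError as exc:
            errors.extend(exc.errors)
    if errors:
        raise AuditValidationError(errors)


# ---------------------------------------------------------------------------
# I/O: long CSV and nested JSON carry the same content


def _audits_to_long_rows(audits: Sequence[SchoolAudit]):
    for audit in audits:
        for unit in audit.all_units():
            for resp in unit.responses:
                yield (
                    audit.school_id, audit.rater_pair_id, unit.unit_id,
                    unit.unit_kind, resp.item_id, resp.value,
                )


def write_audits_csv(audits: Sequence[SchoolAudit], path: Union[str, Path]) -> None:
    df = pd.DataFrame(_audits_to_long_rows(audits), columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def write_audits_json(audits: Sequence[SchoolAudit], path: Union[str, Path]) -> None:
    payload = [
        {
            "school_id": a.school_id,
            "rater_pair_id": a.rater_pair_id,
            "date": a.date,
            "units": [
                {
                    "unit_id": u.unit_id,
                    "unit_kind": u.unit_kind,
                    "responses": {r.item_id: r.value for r in u.responses},
                }
                for u in a.all_units()
            ],
        }
        for a in audits
    ]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _coerce_value(raw, item) -> object:
    """Map a CSV string to the item's domain; raise ValueError when impossible."""
    if isinstance(raw, str) and item.response_domain.kind != "categorical":
        raw = int(raw)
    elif isinstance(raw, float):
        if not float(raw).is_integer():
            raise ValueError(f"non-integer value {raw!r}")
        raw = int(raw)
    return raw


def _assemble(records, schema: ScoringSchema) -> list:
    """records: (school, rater, unit, kind, item, raw_value) tuples."""
    errors: list[str] = []
    units: dict = {}
    order: list = []
    for school, rater, unit_id, kind, item_id, raw in records:
        key = (str(school), str(rater))
        ukey = (key, str(unit_id), str(kind))
        if ukey not in units:
            units[ukey] = {}
            order.append(ukey)
        if not schema.has_item(str(item_id)):
            errors.append(
                f"school {school} unit {unit_id}: unknown item_id {item_id!r}"
            )
            continue
        item = schema.item(str(item_id))
        try:
            value = _coerce_value(raw, item)
        except (ValueError, TypeError):
            errors.append(
                f"school {school} unit {unit_id}: unparseable value {raw!r} "
                f"for {item_id}"
            )
            continue
        units[ukey][str(item_id)] = value
    if errors:
        raise AuditValidationError(errors)

    by_school: dict = {}
    school_order: list = []
    for ukey in sorted(order):
        key, unit_id, kind = ukey
        if key not in by_school:
            by_school[key] = {s: [] for s in SECTIONS}
            school_order.append(key)
        responses = tuple(
            ItemResponse(item_id, value)
            for item_id, value in sorted(units[ukey].items())
        )
        if kind not in by_school[key]:
            by_school[key][kind] = []
        by_school[key][kind].append(UnitAudit(unit_id, kind, responses))

    audits = []
    for key in sorted(school_order):
        school, rater = key
        sections = by_school[key]
        bad_kinds = set(sections) - set(SECTIONS)
        if bad_kinds:
            errors.append(f"school {school}: unknown unit_kind values {sorted(bad_kinds)}")
            continue
        audits.append(
            SchoolAudit(
                school_id=school,
                rater_pair_id=rater,
                access_segments=tuple(sections["school_access_segment"]),
                other_segments=tuple(sections["other_segment"]),
                crossings=tuple(sections["crossing"]),
            )
        )
    if errors:
        raise AuditValidationError(errors)
    validate_audits(audits, schema)
    return audits


def read_audits(path: Union[str, Path], schema: ScoringSchema) -> list:
    """Load audits from long CSV or nested JSON; always fully validated.

    The returned list is sorted by (school_id, rater_pair_id), so row order
    in the file never affects the result.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        records = [
            (a["school_id"], a["rater_pair_id"], u["unit_id"], u["unit_kind"], i, v)
            for a in payload
            for u in a["units"]
            for i, v in u["responses"].items()
        ]
    else:
        df = pd.read_csv(path, dtype={c: str for c in CSV_COLUMNS[:5]})
        missing_cols = set(CSV_COLUMNS) - set(df.columns)
        if missing_cols:
            raise AuditValidationError(
                [f"{path}: missing columns {sorted(missing_cols)}"]
            )
        records = list(df[list(CSV_COLUMNS)].itertuples(index=False, name=None))
    return _assemble(records, schema)


# ---------------------------------------------------------------------------
# rating matrices


def build_rating_matrix(
    audits: Sequence[SchoolAudit],
    subscale_id: str,
    schema: ScoringSchema,
    scorer: Optional[Callable[[SchoolAudit], float]] = None,
) -> RatingMatrix:
    """Assemble the complete schools x rater-pairs score table for a subscale.

    ``scorer`` maps a SchoolAudit to that subscale's score; by default the
    scoring engine is used.  Raises when the design is incomplete (a school
    missing a rater pair) or degenerate (fewer than 2 schools or raters).
    """
    if scorer is None:
        from .scoring import score_school

        def scorer(audit: SchoolAudit) -> float:
            return score_school(audit, schema).subscale_scores[subscale_id]

    schools = sorted({a.school_id for a in audits})
    raters = sorted({a.rater_pair_id for a in audits})
    if len(schools) < 2 or len(raters) < 2:
        raise ValueError(
            f"reliability needs >= 2 schools and >= 2 rater pairs; "
            f"got {len(schools)} x {len(raters)}"
        )
    cells: dict = {}
    for a in audits:
        key = (a.school_id, a.rater_pair_id)
        if key in cells:
            raise ValueError(f"duplicate audit for school {key[0]} rater pair {key[1]}")
        cells[key] = scorer(a)
    values = np.empty((len(schools), len(raters)))
    for i, s in enumerate(schools):
        for j, r in enumerate(raters):
            if (s, r) not in cells:
                raise ValueError(f"incomplete design: school {s} missing rater pair {r}")
            values[i, j] = cells[(s, r)]
    return RatingMatrix(subscale_id, schools, raters, values)
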