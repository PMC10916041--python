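"""Hierarchical scoring: item points -> subscale sums -> section overalls -> total.

Scores are summed across audited units (a school with nine other segments
accumulates nine segments' worth of points), subscale scores sum their
children, each section overall is its positive overall minus its negative
overall, and the total is the sum of the three section overalls.  Higher
totals indicate a streetscape more supportive of walking and bicycling to
school.

The road-width subscale is the one node that does not sum item points: it
recodes the two lane-count items per crossing.  The final instrument uses a
dichotomy (one negative point when a crossing spans more than 4 total
lanes); the initial instrument used a trichotomy of the lane total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .audits import SchoolAudit, UnitAudit, validate_audit
from .schema import SECTIONS, ItemDef, ScoringSchema, SubscaleDef


@dataclass(frozen=True)
class ScoreReport:
    school_id: str
    rater_pair_id: str
    subscale_scores: Mapping  # subscale_id -> score (includes overalls and total)
    section_overalls: Mapping  # section -> score
    total: float


def score_item(item: ItemDef, value) -> float:
    """Points for one response, straight from the item's score map."""
    if value not in item.response_domain:
        raise ValueError(
            f"value {value!r} outside the {item.response_domain.kind} domain "
            f"of item {item.item_id}"
        )
    return item.score_map[value]


def dichotomize_road_width(travel_lanes: int, turn_lanes: int) -> int:
    """1 negative point iff the crossing spans more than 4 total lanes."""
    if travel_lanes < 0 or turn_lanes < 0:
        raise ValueError("lane counts must be nonnegative")
    return 1 if travel_lanes + turn_lanes > 4 else 0


def trichotomize_road_width(travel_lanes: int, turn_lanes: int) -> int:
    """Initial-version trichotomy of the lane total: <=2 / 3-4 / >=5 lanes."""
    if travel_lanes < 0 or turn_lanes < 0:
        raise ValueError("lane counts must be nonnegative")
    total = travel_lanes + turn_lanes
    if total <= 2:
        return 0
    return 1 if total <= 4 else 2


def _recode_lanes_dichotomous(values: Mapping) -> float:
    return dichotomize_road_width(values["crs_travel_lanes"], values["crs_turn_lanes"])


def _recode_lanes_trichotomous(values: Mapping) -> float:
    return trichotomize_road_width(values["crs_travel_lanes"], values["crs_turn_lanes"])


#: unit-level recodes addressable from SubscaleDef.recode
RECODES = {
    "lanes_dichotomous_gt4": _recode_lanes_dichotomous,
    "lanes_trichotomous": _recode_lanes_trichotomous,
}


def score_subscale(
    subscale: SubscaleDef,
    unit_audits: Sequence[UnitAudit],
    schema: ScoringSchema,
) -> float:
    """Leaf subscale score: sum over audited units of child-item points."""
    if not schema.is_leaf(subscale.subscale_id):
        raise ValueError(f"{subscale.subscale_id} is not a leaf subscale")
    for unit in unit_audits:
        if unit.unit_kind != subscale.section:
            raise ValueError(
                f"unit {unit.unit_id} has kind {unit.unit_kind!r}; subscale "
                f"{subscale.subscale_id} belongs to section {subscale.section!r}"
            )
    recode = RECODES[subscale.recode] if subscale.recode else None
    total = 0.0
    for unit in unit_audits:
        values = unit.response_map()
        if recode is not None:
            total += recode(values)
        else:
            for item_id in subscale.children:
                total += score_item(schema.item(item_id), values[item_id])
    return total


def score_school(
    audit: SchoolAudit, schema: ScoringSchema, validate: bool = True
) -> ScoreReport:
    """Full hierarchical score report for one school audit."""
    if validate:
        validate_audit(audit, schema)
    scores: dict = {}

    def walk(subscale_id: str) -> float:
        if subscale_id in scores:
            return scores[subscale_id]
        sub = schema.subscale(subscale_id)
        if schema.is_leaf(subscale_id):
            value = score_subscale(sub, audit.units_for_section(sub.section), schema)
        elif sub.aggregation == "positive_minus_negative":
            pos, neg = (schema.subscale(c) for c in sub.children)
            if pos.valence != "positive":
                pos, neg = neg, pos
            value = walk(pos.subscale_id) - walk(neg.subscale_id)
        else:  # sum_children / sum_sections over subscale children
            value = sum(walk(c) for c in sub.children)
        scores[subscale_id] = value
        return value

    total = walk(schema.total_id)
    for sub in schema.subscales:  # anything not under the total still gets scored
        walk(sub.subscale_id)

    section_overalls = {
        sec: scores[schema.section_overall_id(sec)] for sec in SECTIONS
    }
    return ScoreReport(
        school_id=audit.school_id,
        rater_pair_id=audit.rater_pair_id,
        subscale_scores=scores,
        section_overalls=section_overalls,
        total=total,
    )
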