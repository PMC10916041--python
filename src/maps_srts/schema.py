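"""Instrument definition: items, subscales, and the aggregation tree.

The MAPS-SRTS audit instrument is represented as a :class:`ScoringSchema`:
a flat list of :class:`ItemDef` (the questions raters answer in the field)
plus a hierarchy of :class:`SubscaleDef` nodes that aggregate item points
into subscale scores, positive/negative section overalls, and the total
score.  Two schema versions exist: ``initial_v1`` (30 non-total subscales,
as first proposed) and ``final_v2`` (26 subscales, after the reliability
driven removals and the road-width recode).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

SECTIONS = ("school_access_segment", "other_segment", "crossing")
VERSIONS = ("initial_v1", "final_v2")
VALENCES = ("positive", "negative", "unscored")
SUBSCALE_VALENCES = ("positive", "negative", "composite")
AGGREGATIONS = ("sum_children", "positive_minus_negative", "sum_sections")
STATUSES = ("retained", "removed", "revised")


class SchemaError(ValueError):
    """Malformed or internally inconsistent scoring schema."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class ResponseDomain:
    """Set of legal responses for one item.

    kind: 'binary' (0/1), 'ordinal' (0..L-1), 'count' (0..max),
    or 'categorical' (explicit level labels).
    """

    kind: str
    levels: tuple

    @staticmethod
    def binary() -> "ResponseDomain":
        return ResponseDomain("binary", (0, 1))

    @staticmethod
    def ordinal(n_levels: int) -> "ResponseDomain":
        return ResponseDomain("ordinal", tuple(range(n_levels)))

    @staticmethod
    def count(max_value: int = 10) -> "ResponseDomain":
        return ResponseDomain("count", tuple(range(max_value + 1)))

    @staticmethod
    def categorical(levels: Sequence[str]) -> "ResponseDomain":
        return ResponseDomain("categorical", tuple(levels))

    def __contains__(self, value) -> bool:
        return value in self.levels


@dataclass(frozen=True)
class ItemDef:
    item_id: str
    section: str
    prompt: str
    response_domain: ResponseDomain
    score_map: Mapping
    valence: str  # positive | negative | unscored
    subscale_id: Optional[str] = None


@dataclass(frozen=True)
class SubscaleDef:
    subscale_id: str
    section: str  # one of SECTIONS or 'total'
    valence: str  # positive | negative | composite
    children: tuple  # all item_ids or all subscale_ids, never mixed
    aggregation: str
    status: str = "retained"
    counterpart_id: Optional[str] = None
    recode: Optional[str] = None  # name of a registered unit-level recode


@dataclass(frozen=True)
class ChangeRecord:
    kind: str  # added | removed | revised
    subscale_id: str


@dataclass
class ScoringSchema:
    version: str
    items: list = field(default_factory=list)
    subscales: list = field(default_factory=list)
    total_id: str = "maps_srts_total"

    def __post_init__(self):
        self._items_by_id = {it.item_id: it for it in self.items}
        self._subscales_by_id = {s.subscale_id: s for s in self.subscales}

    # -- lookups -----------------------------------------------------------
    def item(self, item_id: str) -> ItemDef:
        try:
            return self._items_by_id[item_id]
        except KeyError:
            raise KeyError(f"unknown item_id: {item_id!r}") from None

    def subscale(self, subscale_id: str) -> SubscaleDef:
        try:
            return self._subscales_by_id[subscale_id]
        except KeyError:
            raise KeyError(f"unknown subscale_id: {subscale_id!r}") from None

    def has_item(self, item_id: str) -> bool:
        return item_id in self._items_by_id

    def items_for_section(self, section: str) -> list:
        if section not in SECTIONS:
            raise ValueError(f"unknown section: {section!r}")
        return [it for it in self.items if it.section == section]

    def scored_items_for_section(self, section: str) -> list:
        return [
            it for it in self.items_for_section(section) if it.subscale_id is not None
        ]

    def non_total_subscales(self) -> list:
        return [s for s in self.subscales if s.subscale_id != self.total_id]

    def leaf_subscales(self) -> list:
        """Subscales whose children are items."""
        return [s for s in self.subscales if self.is_leaf(s.subscale_id)]

    def is_leaf(self, subscale_id: str) -> bool:
        sub = self.subscale(subscale_id)
        return bool(sub.children) and sub.children[0] in self._items_by_id

    def section_overall_id(self, section: str) -> str:
        total = self.subscale(self.total_id)
        for child in total.children:
            if self.subscale(child).section == section:
                return child
        raise KeyError(f"no section overall for {section!r}")

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`SchemaError` listing every invariant violation."""
        errors: list[str] = []
        seen_items: set[str] = set()
        for it in self.items:
            if it.item_id in seen_items:
                errors.append(f"duplicate item_id: {it.item_id}")
            seen_items.add(it.item_id)
            if it.section not in SECTIONS:
                errors.append(f"item {it.item_id}: bad section {it.section!r}")
            if it.valence not in VALENCES:
                errors.append(f"item {it.item_id}: bad valence {it.valence!r}")
            missing = [v for v in it.response_domain.levels if v not in it.score_map]
            extra = [v for v in it.score_map if v not in it.response_domain.levels]
            if missing or extra:
                errors.append(
                    f"item {it.item_id}: score_map does not cover response "
                    f"domain exactly (missing={missing}, extra={extra})"
                )
            if it.subscale_id is not None and it.valence == "unscored":
                errors.append(
                    f"item {it.item_id}: attached to {it.subscale_id} but unscored"
                )
            if it.subscale_id is not None and it.subscale_id not in self._subscales_by_id:
                errors.append(
                    f"item {it.item_id}: unknown subscale_id {it.subscale_id!r}"
                )

        seen_subs: set[str] = set()
        for sub in self.subscales:
            if sub.subscale_id in seen_subs:
                errors.append(f"duplicate subscale_id: {sub.subscale_id}")
            seen_subs.add(sub.subscale_id)
            if sub.section not in SECTIONS + ("total",):
                errors.append(f"subscale {sub.subscale_id}: bad section {sub.section!r}")
            if sub.valence not in SUBSCALE_VALENCES:
                errors.append(f"subscale {sub.subscale_id}: bad valence {sub.valence!r}")
            if sub.aggregation not in AGGREGATIONS:
                errors.append(
                    f"subscale {sub.subscale_id}: bad aggregation {sub.aggregation!r}"
                )
            kinds = {
                "item" if c in self._items_by_id
                else "subscale" if c in self._subscales_by_id
                else "unknown"
                for c in sub.children
            }
            if "unknown" in kinds:
                bad = [
                    c for c in sub.children
                    if c not in self._items_by_id and c not in self._subscales_by_id
                ]
                errors.append(f"subscale {sub.subscale_id}: unresolved children {bad}")
            elif len(kinds) > 1:
                errors.append(f"subscale {sub.subscale_id}: mixed item/subscale children")
            if sub.valence == "composite" and sub.aggregation == "sum_children":
                errors.append(
                    f"subscale {sub.subscale_id}: composite valence on a plain sum node"
                )
            if sub.aggregation == "positive_minus_negative":
                vals = sorted(
                    self._subscales_by_id[c].valence
                    for c in sub.children
                    if c in self._subscales_by_id
                )
                if vals != ["negative", "positive"]:
                    errors.append(
                        f"subscale {sub.subscale_id}: positive_minus_negative needs "
                        f"exactly one positive and one negative child, got {vals}"
                    )
            if sub.counterpart_id is not None:
                if sub.counterpart_id not in self._subscales_by_id:
                    errors.append(
                        f"subscale {sub.subscale_id}: unknown counterpart "
                        f"{sub.counterpart_id!r}"
                    )

        if self.total_id not in self._subscales_by_id:
            errors.append(f"total_id {self.total_id!r} not among subscales")
        else:
            errors.extend(self._check_tree())

        if errors:
            raise SchemaError(errors)

    def _check_tree(self) -> list:
        """Acyclicity of the aggregation tree and reachability of retained nodes."""
        errors: list[str] = []
        visited: set[str] = set()
        stack: set[str] = set()

        def walk(sid: str) -> None:
            if sid in stack:
                errors.append(f"aggregation cycle through {sid}")
                return
            if sid in visited:
                return
            visited.add(sid)
            stack.add(sid)
            sub = self._subscales_by_id.get(sid)
            if sub is not None:
                for c in sub.children:
                    if c in self._subscales_by_id:
                        walk(c)
            stack.discard(sid)

        walk(self.total_id)
        for sub in self.subscales:
            if sub.status != "removed" and sub.subscale_id not in visited:
                errors.append(
                    f"retained subscale {sub.subscale_id} unreachable from total"
                )
        return errors

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "total_id": self.total_id,
            "items": [
                {
                    "item_id": it.item_id,
                    "section": it.section,
                    "prompt": it.prompt,
                    "response_domain": {
                        "kind": it.response_domain.kind,
                        "levels": list(it.response_domain.levels),
                    },
                    "score_map": {str(k): v for k, v in it.score_map.items()},
                    "valence": it.valence,
                    "subscale_id": it.subscale_id,
                }
                for it in self.items
            ],
            "subscales": [
                {
                    "subscale_id": s.subscale_id,
                    "section": s.section,
                    "valence": s.valence,
                    "children": list(s.children),
                    "aggregation": s.aggregation,
                    "status": s.status,
                    "counterpart_id": s.counterpart_id,
                    "recode": s.recode,
                }
                for s in self.subscales
            ],
        }

    @staticmethod
    def from_dict(data: Mapping) -> "ScoringSchema":
        def parse_item(rec: Mapping) -> ItemDef:
            dom = ResponseDomain(
                rec["response_domain"]["kind"],
                tuple(rec["response_domain"]["levels"]),
            )
            key_type = type(dom.levels[0]) if dom.levels else str
            score_map = {
                (key_type(k) if key_type is not str else k): v
                for k, v in rec["score_map"].items()
            }
            return ItemDef(
                item_id=rec["item_id"],
                section=rec["section"],
                prompt=rec.get("prompt", ""),
                response_domain=dom,
                score_map=score_map,
                valence=rec["valence"],
                subscale_id=rec.get("subscale_id"),
            )

        try:
            items = [parse_item(rec) for rec in data["items"]]
            subscales = [
                SubscaleDef(
                    subscale_id=rec["subscale_id"],
                    section=rec["section"],
                    valence=rec["valence"],
                    children=tuple(rec["children"]),
                    aggregation=rec["aggregation"],
                    status=rec.get("status", "retained"),
                    counterpart_id=rec.get("counterpart_id"),
                    recode=rec.get("recode"),
                )
                for rec in data["subscales"]
            ]
        except (KeyError, TypeError, IndexError) as exc:
            raise SchemaError([f"malformed schema record: {exc!r}"]) from exc
        return ScoringSchema(
            version=data.get("version", "final_v2"),
            items=items,
            subscales=subscales,
            total_id=data.get("total_id", "maps_srts_total"),
        )


# ---------------------------------------------------------------------------
# file I/O


def save_schema(schema: ScoringSchema, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(schema.to_dict(), indent=1, sort_keys=True))


def load_schema(path: Union[str, Path], version: Optional[str] = None) -> ScoringSchema:
    """Load and validate a schema JSON file.

    When ``version`` is given it must match the file's declared version.
    """
    if version is not None and version not in VERSIONS:
        raise ValueError(f"unsupported version {version!r}; expected one of {VERSIONS}")
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError([f"cannot parse {path}: {exc}"]) from exc
    schema = ScoringSchema.from_dict(data)
    if version is not None and schema.version != version:
        raise SchemaError(
            [f"file declares version {schema.version!r}, requested {version!r}"]
        )
    schema.validate()
    return schema


def count_items(schema: ScoringSchema, section: str) -> int:
    """Number of items in one audit section."""
    return len(schema.items_for_section(section))


def diff_versions(a: ScoringSchema, b: ScoringSchema) -> list:
    """Subscale-level change list turning ``a``'s subscale set into ``b``'s.

    A subscale present in both counts as revised when its recode, children,
    or status differ.
    """
    sections_a = {s.section for s in a.subscales}
    sections_b = {s.section for s in b.subscales}
    if sections_a != sections_b:
        raise ValueError(
            f"schemas use different section vocabularies: {sections_a} vs {sections_b}"
        )
    ids_a = {s.subscale_id for s in a.subscales}
    ids_b = {s.subscale_id for s in b.subscales}
    changes = [ChangeRecord("removed", sid) for sid in sorted(ids_a - ids_b)]
    changes += [ChangeRecord("added", sid) for sid in sorted(ids_b - ids_a)]
    shared = ids_a & ids_b
    for sid in sorted(shared):
        sa, sb = a.subscale(sid), b.subscale(sid)
        # Child lists are compared ignoring subscales absent from the other
        # version: a parent shrinking because a child was removed is a
        # consequence of that removal, not an independent revision.
        ca = tuple(c for c in sa.children if c in shared or a.has_item(c))
        cb = tuple(c for c in sb.children if c in shared or b.has_item(c))
        if (sa.recode, ca) != (sb.recode, cb):
            changes.append(ChangeRecord("revised", sid))
    return changes


# ---------------------------------------------------------------------------
# CSV data dictionary (items only; the subscale tree stays in JSON)

_CSV_COLUMNS = (
    "item_id", "section", "prompt", "response_domain", "score_map", "valence",
    "subscale_id",
)


def items_to_csv(schema: ScoringSchema, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
        writer.writeheader()
        for it in schema.items:
            dom = it.response_domain
            writer.writerow(
                {
                    "item_id": it.item_id,
                    "section": it.section,
                    "prompt": it.prompt,
                    "response_domain": f"{dom.kind}:{len(dom.levels)}",
                    "score_map": json.dumps(
                        {str(k): v for k, v in it.score_map.items()}
                    ),
                    "valence": it.valence,
                    "subscale_id": it.subscale_id or "",
                }
            )


def items_from_csv(path: Union[str, Path]) -> list:
    """Read ItemDefs from a CSV data dictionary (inverse of items_to_csv)."""
    items = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            kind, _, n = row["response_domain"].partition(":")
            n_levels = int(n)
            if kind == "binary":
                dom = ResponseDomain.binary()
            elif kind == "ordinal":
                dom = ResponseDomain.ordinal(n_levels)
            elif kind == "count":
                dom = ResponseDomain.count(n_levels - 1)
            else:
                raise SchemaError(
                    [f"item {row['item_id']}: unsupported CSV domain {kind!r}"]
                )
            raw_map = json.loads(row["score_map"])
            items.append(
                ItemDef(
                    item_id=row["item_id"],
                    section=row["section"],
                    prompt=row["prompt"],
                    response_domain=dom,
                    score_map={int(k): v for k, v in raw_map.items()},
                    valence=row["valence"],
                    subscale_id=row["subscale_id"] or None,
                )
            )
    return items
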