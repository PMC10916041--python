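"""Shipped default MAPS-SRTS data dictionary.

The instrument has 90 items across three audit sections — 33 on the school
access segment, 30 on other segments near the school, 27 on crossings.
Both segment sections share the same scored item content (the school access
section adds a few school-specific unscored items); each school-access
subscale therefore has a same-content counterpart in the other-segment
section, which the reliability retention rules exploit.

``initial_v1`` carries 30 non-total subscales (11 school access, 11 other
segment, 8 crossing).  ``final_v2`` drops the positive buffer and positive
shade subscales from both segment sections (their items stay in the
instrument as unscored) and recodes road width from a trichotomy of total
lanes to a dichotomy at more than 4 total lanes, leaving 26 subscales
(9 / 9 / 8).

Only item counts per subscale and the aggregation tree are constrained by
the published instrument; item wording beyond the sampled prompts is
paraphrased or neutral placeholder text.
"""

from __future__ import annotations

from .schema import ItemDef, ResponseDomain, ScoringSchema, SubscaleDef

_BINARY = ResponseDomain.binary()
_BINARY_MAP = {0: 0, 1: 1}

# (stem, prompt) pairs shared by both segment sections, keyed by subscale stem.
_SEGMENT_SCORED = {
    "positive_streetscape": [
        ("public_transit_stop", "Public transit stop on the segment"),
        ("posted_speed_limit_sign", "Posted speed limit sign present"),
        ("speed_restriction_sign", "Speed restriction signage present"),
        ("traffic_calming_feature", "Traffic calming feature (hump, chicane, ...)"),
        ("instructional_sign", "Instructional or wayfinding sign present"),
        ("streetlights", "Streetlights present along the segment"),
        ("street_amenities", "Street amenities (benches, fountains, art)"),
        ("school_zone_signage", "School zone signage present"),
        ("special_speed_zone_signage", "Special speed zone signage for school hours"),
        ("crossing_guard_station", "Marked crossing-guard station"),
        ("pedestrian_scale_lighting", "Pedestrian-scale lighting present"),
    ],
    "positive_sidewalk": [
        ("sidewalk_present", "Sidewalk present on the audited side"),
        ("sidewalk_width_adequate", "Sidewalk wide enough for two pedestrians"),
        ("alternative_walkway", "Usable alternative walkway or path"),
    ],
    "positive_bicycle_infrastructure": [
        ("bicycle_infrastructure", "Bicycle lane: none / marked / marked with barrier"),
    ],
    "positive_buffer": [
        ("sidewalk_buffer_present", "Sidewalk separated from roadway by a buffer"),
    ],
    "positive_shade": [
        ("sidewalk_shade_coverage", "Share of walkway shaded: 0 / 1-25% / 26-75% / 76-100%"),
    ],
    "negative_streetscape": [
        ("high_speed_limit", "Posted speed limit 30 mph or higher"),
        ("drivers_present", "Moving motor traffic present during audit"),
    ],
    "negative_sidewalk": [
        ("sidewalk_discontinuous", "Sidewalk non-continuous along the segment"),
        ("major_trip_hazard", "Major trip hazard on the walkway"),
    ],
    "negative_aesthetics": [
        ("signs_of_neglect", "Signs of neglect (graffiti, poorly maintained buildings)"),
    ],
}

# Ordinal domains for the two non-binary segment items.
_SEGMENT_ORDINAL = {
    "bicycle_infrastructure": 3,
    "sidewalk_shade_coverage": 4,
}

# Collected on both segment sections but not aggregated into any subscale.
_SEGMENT_UNSCORED = [
    ("construction_present", "Construction work on the segment"),
    ("litter_present", "Noticeable litter on the segment"),
    ("abandoned_vehicles", "Abandoned vehicle on the segment"),
    ("unattended_dogs", "Unattended dogs on the segment"),
    ("street_wall_continuity", "Continuous building frontage along the segment"),
    ("on_street_parking", "On-street parking permitted"),
    ("driveway_curb_cuts", "Driveway curb cuts interrupting the walkway"),
    ("overhead_utility_poles", "Overhead utility poles in the walkway"),
]

# Extra school-specific unscored items: only on the school access segment.
_ACCESS_ONLY_UNSCORED = [
    ("school_entrance_visible", "Main school entrance visible from the street"),
    ("drop_off_zone_marked", "Marked vehicle drop-off / pick-up zone"),
    ("bike_racks_visible", "Bicycle racks visible from the street"),
]

_CROSSING_SCORED = {
    "positive_crosswalk_amenities": [
        ("crossing_aid", "Crossing aid present (flags, flashing beacon)"),
        ("marked_crosswalk", "Marked pedestrian crosswalk"),
        ("high_visibility_striping", "High-visibility crosswalk striping"),
        ("stop_line_or_warning", "Stop lines or crosswalk warning markings"),
        ("raised_or_contrasting_crosswalk", "Raised crosswalk or material differing from road"),
        ("protected_refuge_island", "Protected pedestrian refuge island"),
        ("curb_extension", "Curb extension narrowing the crossing"),
    ],
    "curbs": [
        ("curb_ramp_present", "Curb ramp present at the crossing"),
        ("curb_ramp_aligned", "Curb ramp lines up with the crossing"),
    ],
    "positive_intersection_control": [
        ("yield_sign", "Yield sign controlling the crossing"),
        ("stop_sign", "Stop sign controlling the crossing"),
        ("traffic_signal", "Traffic signal at the crossing"),
        ("traffic_circle", "Traffic circle at the intersection"),
        ("green_turn_arrow", "Protected green arrow for turn lane"),
        ("pedestrian_walk_signal", "Pedestrian walk signal present"),
        ("push_button", "Pedestrian push button present"),
        ("countdown_signal", "Countdown pedestrian signal"),
    ],
    "road_width": [
        ("travel_lanes", "Number of travel lanes crossed"),
        ("turn_lanes", "Number of turn lanes crossed"),
    ],
    "negative_crossing_impediments": [
        ("no_ramp_pre_crossing", "No curb ramp before the crossing"),
        ("no_ramp_post_crossing", "No curb ramp after the crossing"),
        ("crossing_poor_condition", "Crosswalk markings in poor condition"),
        ("crossing_obstruction", "Obstruction in the crossing or ramp"),
    ],
}

_CROSSING_UNSCORED = [
    ("angled_crossing", "Crossing meets the road at an angle"),
    ("multi_leg_crossing", "Crossing spans more than two legs"),
    ("rail_crossing", "Rail or tram tracks in the crossing"),
    ("shared_driveway_crossing", "Crossing shared with a commercial driveway"),
]

_NEGATIVE_SEGMENT_SUBSCALES = {
    "negative_streetscape", "negative_sidewalk", "negative_aesthetics",
}

_SECTION_PREFIX = {
    "school_access_segment": "sas",
    "other_segment": "seg",
    "crossing": "crs",
}

TOTAL_ID = "maps_srts_total"


def _segment_items(section: str, version: str) -> list:
    prefix = _SECTION_PREFIX[section]
    items = []
    removed_in_v2 = {"positive_buffer", "positive_shade"}
    for stem, defs in _SEGMENT_SCORED.items():
        valence = "negative" if stem in _NEGATIVE_SEGMENT_SUBSCALES else "positive"
        subscale_id = f"{prefix}_{stem}"
        unscored = version == "final_v2" and stem in removed_in_v2
        for name, prompt in defs:
            if name in _SEGMENT_ORDINAL:
                dom = ResponseDomain.ordinal(_SEGMENT_ORDINAL[name])
                score_map = {lvl: lvl for lvl in dom.levels}
            else:
                dom, score_map = _BINARY, _BINARY_MAP
            items.append(
                ItemDef(
                    item_id=f"{prefix}_{name}",
                    section=section,
                    prompt=prompt,
                    response_domain=dom,
                    score_map=score_map,
                    valence="unscored" if unscored else valence,
                    subscale_id=None if unscored else subscale_id,
                )
            )
    extras = list(_SEGMENT_UNSCORED)
    if section == "school_access_segment":
        extras += _ACCESS_ONLY_UNSCORED
    for name, prompt in extras:
        items.append(
            ItemDef(
                item_id=f"{prefix}_{name}",
                section=section,
                prompt=prompt,
                response_domain=_BINARY,
                score_map=_BINARY_MAP,
                valence="unscored",
                subscale_id=None,
            )
        )
    return items


def _crossing_items() -> list:
    items = []
    for stem, defs in _CROSSING_SCORED.items():
        valence = (
            "negative"
            if stem in {"road_width", "negative_crossing_impediments"}
            else "positive"
        )
        for name, prompt in defs:
            if stem == "road_width":
                dom = ResponseDomain.count(10)
                score_map = {v: v for v in dom.levels}
            else:
                dom, score_map = _BINARY, _BINARY_MAP
            items.append(
                ItemDef(
                    item_id=f"crs_{name}",
                    section="crossing",
                    prompt=prompt,
                    response_domain=dom,
                    score_map=score_map,
                    valence=valence,
                    subscale_id=f"crs_{stem}",
                )
            )
    for name, prompt in _CROSSING_UNSCORED:
        items.append(
            ItemDef(
                item_id=f"crs_{name}",
                section="crossing",
                prompt=prompt,
                response_domain=_BINARY,
                score_map=_BINARY_MAP,
                valence="unscored",
                subscale_id=None,
            )
        )
    return items


def _segment_subscales(section: str, version: str) -> list:
    prefix = _SECTION_PREFIX[section]
    other = "seg" if prefix == "sas" else "sas"
    removed_in_v2 = {"positive_buffer", "positive_shade"}
    subs = []
    positive_leaves = [
        "positive_streetscape", "positive_sidewalk", "positive_bicycle_infrastructure",
        "positive_buffer", "positive_shade",
    ]
    negative_leaves = ["negative_streetscape", "negative_sidewalk", "negative_aesthetics"]
    kept_positive = [
        s for s in positive_leaves
        if version == "initial_v1" or s not in removed_in_v2
    ]
    for stem in kept_positive + negative_leaves:
        valence = "negative" if stem in _NEGATIVE_SEGMENT_SUBSCALES else "positive"
        subs.append(
            SubscaleDef(
                subscale_id=f"{prefix}_{stem}",
                section=section,
                valence=valence,
                children=tuple(
                    f"{prefix}_{name}" for name, _ in _SEGMENT_SCORED[stem]
                ),
                aggregation="sum_children",
                counterpart_id=f"{other}_{stem}",
            )
        )
    subs.append(
        SubscaleDef(
            subscale_id=f"{prefix}_overall_positive",
            section=section,
            valence="positive",
            children=tuple(f"{prefix}_{s}" for s in kept_positive),
            aggregation="sum_children",
            counterpart_id=f"{other}_overall_positive",
        )
    )
    subs.append(
        SubscaleDef(
            subscale_id=f"{prefix}_overall_negative",
            section=section,
            valence="negative",
            children=tuple(f"{prefix}_{s}" for s in negative_leaves),
            aggregation="sum_children",
            counterpart_id=f"{other}_overall_negative",
        )
    )
    subs.append(
        SubscaleDef(
            subscale_id=f"{prefix}_overall",
            section=section,
            valence="composite",
            children=(f"{prefix}_overall_positive", f"{prefix}_overall_negative"),
            aggregation="positive_minus_negative",
            counterpart_id=f"{other}_overall",
        )
    )
    return subs


def _crossing_subscales(version: str) -> list:
    subs = []
    for stem in ["positive_crosswalk_amenities", "curbs", "positive_intersection_control"]:
        subs.append(
            SubscaleDef(
                subscale_id=f"crs_{stem}",
                section="crossing",
                valence="positive",
                children=tuple(f"crs_{name}" for name, _ in _CROSSING_SCORED[stem]),
                aggregation="sum_children",
            )
        )
    subs.append(
        SubscaleDef(
            subscale_id="crs_road_width",
            section="crossing",
            valence="negative",
            children=("crs_travel_lanes", "crs_turn_lanes"),
            aggregation="sum_children",
            status="revised" if version == "final_v2" else "retained",
            recode=(
                "lanes_dichotomous_gt4" if version == "final_v2"
                else "lanes_trichotomous"
            ),
        )
    )
    subs.append(
        SubscaleDef(
            subscale_id="crs_negative_crossing_impediments",
            section="crossing",
            valence="negative",
            children=tuple(
                f"crs_{name}" for name, _ in
                _CROSSING_SCORED["negative_crossing_impediments"]
            ),
            aggregation="sum_children",
        )
    )
    subs.append(
        SubscaleDef(
            subscale_id="crs_overall_positive",
            section="crossing",
            valence="positive",
            children=(
                "crs_positive_crosswalk_amenities", "crs_curbs",
                "crs_positive_intersection_control",
            ),
            aggregation="sum_children",
        )
    )
    subs.append(
        SubscaleDef(
            subscale_id="crs_overall_negative",
            section="crossing",
            valence="negative",
            children=("crs_road_width", "crs_negative_crossing_impediments"),
            aggregation="sum_children",
        )
    )
    subs.append(
        SubscaleDef(
            subscale_id="crs_overall",
            section="crossing",
            valence="composite",
            children=("crs_overall_positive", "crs_overall_negative"),
            aggregation="positive_minus_negative",
        )
    )
    return subs


def default_schema(version: str = "final_v2") -> ScoringSchema:
    """Build the shipped MAPS-SRTS dictionary for one schema version."""
    if version not in ("initial_v1", "final_v2"):
        raise ValueError(f"unsupported version {version!r}")
    items = (
        _segment_items("school_access_segment", version)
        + _segment_items("other_segment", version)
        + _crossing_items()
    )
    subscales = (
        _segment_subscales("school_access_segment", version)
        + _segment_subscales("other_segment", version)
        + _crossing_subscales(version)
    )
    subscales.append(
        SubscaleDef(
            subscale_id=TOTAL_ID,
            section="total",
            valence="composite",
            children=("sas_overall", "seg_overall", "crs_overall"),
            aggregation="sum_sections",
        )
    )
    schema = ScoringSchema(version=version, items=items, subscales=subscales,
                           total_id=TOTAL_ID)
    schema.validate()
    return schema
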