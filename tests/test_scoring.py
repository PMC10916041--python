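"""Hierarchical scoring: contracts, monotonicity, and the tree-walk oracle."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maps_srts import (
    ItemResponse, SchoolAudit, UnitAudit, dichotomize_road_width, score_item,
    score_school, score_subscale, trichotomize_road_width,
)
from maps_srts.schema import SECTIONS

from conftest import naive_score_report, random_audit, random_unit


def test_score_item_examples(schema_v2):
    binary = schema_v2.item("sas_sidewalk_present")
    assert score_item(binary, 1) == 1
    assert score_item(binary, 0) == 0
    shade = schema_v2.item("sas_sidewalk_shade_coverage")
    assert score_item(shade, 2) == 2
    with pytest.raises(ValueError, match="outside"):
        score_item(binary, 7)


@pytest.mark.parametrize("travel", range(11))
@pytest.mark.parametrize("turn", range(11))
def test_road_width_dichotomy_matches_published_rule(travel, turn):
    assert dichotomize_road_width(travel, turn) == (1 if travel + turn > 4 else 0)


def test_road_width_rejects_negative_lanes():
    with pytest.raises(ValueError):
        dichotomize_road_width(-1, 0)
    with pytest.raises(ValueError):
        trichotomize_road_width(0, -2)


def test_trichotomy_is_monotone_in_total_lanes():
    codes = [trichotomize_road_width(t, 0) for t in range(11)]
    assert codes == sorted(codes) and set(codes) == {0, 1, 2}


def test_score_subscale_sum_and_linearity(schema_v2):
    sub = schema_v2.subscale("sas_positive_streetscape")
    all_present = tuple(
        ItemResponse(it.item_id, it.response_domain.levels[-1])
        for it in schema_v2.items_for_section("school_access_segment")
    )
    unit = UnitAudit("u1", "school_access_segment", all_present)
    assert score_subscale(sub, [unit], schema_v2) == 11  # 11 binary items present
    assert score_subscale(sub, [unit, unit], schema_v2) == 22  # sums across units
    assert score_subscale(sub, [], schema_v2) == 0


def test_score_subscale_rejects_unit_kind_mismatch(schema_v2):
    sub = schema_v2.subscale("sas_positive_streetscape")
    rng = np.random.default_rng(0)
    wrong = random_unit(schema_v2, "crossing", "c1", rng)
    with pytest.raises(ValueError, match="kind"):
        score_subscale(sub, [wrong], schema_v2)


def test_all_zero_audit_scores_zero(schema_v2):
    def zero_unit(section, uid):
        return UnitAudit(
            uid, section,
            tuple(
                ItemResponse(it.item_id, it.response_domain.levels[0])
                for it in schema_v2.items_for_section(section)
            ),
        )

    audit = SchoolAudit(
        school_id="s", rater_pair_id="p",
        access_segments=(zero_unit("school_access_segment", "a0"),),
        other_segments=(zero_unit("other_segment", "o0"),),
        crossings=(zero_unit("crossing", "c0"),),
    )
    report = score_school(audit, schema_v2)
    assert report.total == 0
    assert all(v == 0 for v in report.subscale_scores.values())


@pytest.mark.parametrize("version", ["initial_v1", "final_v2"])
@pytest.mark.parametrize("seed", range(6))
def test_report_matches_naive_tree_walk_oracle(version, seed):
    from maps_srts import default_schema

    schema = default_schema(version)
    rng = np.random.default_rng(seed)
    audit = random_audit(schema, rng, n_other=3, n_crossings=3)
    report = score_school(audit, schema)
    oracle = naive_score_report(audit, schema)
    assert set(report.subscale_scores) == set(oracle)
    for sid, value in oracle.items():
        assert report.subscale_scores[sid] == pytest.approx(value)


@pytest.mark.parametrize("seed", range(4))
def test_section_decomposition_and_overall_contract(schema_v2, seed):
    rng = np.random.default_rng(100 + seed)
    audit = random_audit(schema_v2, rng)
    report = score_school(audit, schema_v2)
    assert report.total == pytest.approx(sum(report.section_overalls.values()))
    for section in SECTIONS:
        overall = schema_v2.subscale(schema_v2.section_overall_id(section))
        pos, neg = overall.children
        if schema_v2.subscale(pos).valence != "positive":
            pos, neg = neg, pos
        assert report.section_overalls[section] == pytest.approx(
            report.subscale_scores[pos] - report.subscale_scores[neg]
        )


def _flip_item(audit, schema, item, delta):
    """Return a copy of the audit with one response nudged by delta."""
    section = item.section
    units = list(audit.units_for_section(section))
    unit = units[0]
    new_responses = []
    for resp in unit.responses:
        if resp.item_id == item.item_id:
            levels = item.response_domain.levels
            idx = levels.index(resp.value)
            new_idx = min(max(idx + delta, 0), len(levels) - 1)
            new_responses.append(ItemResponse(resp.item_id, levels[new_idx]))
        else:
            new_responses.append(resp)
    units[0] = UnitAudit(unit.unit_id, unit.unit_kind, tuple(new_responses))
    kwargs = {
        "school_access_segment": "access_segments",
        "other_segment": "other_segments",
        "crossing": "crossings",
    }
    return dataclasses.replace(audit, **{kwargs[section]: tuple(units)})


@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=st.data())
def test_monotonicity_under_single_item_changes(schema_v2, data):
    """Raising a positive item never lowers any score above it; raising a
    negative item never raises the total."""
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    audit = random_audit(schema_v2, rng, n_other=1, n_crossings=1)
    scored = [it for it in schema_v2.items if it.subscale_id is not None]
    item = data.draw(st.sampled_from(scored))
    before = score_school(audit, schema_v2, validate=False)
    after = score_school(
        _flip_item(audit, schema_v2, item, +1), schema_v2, validate=False
    )
    if item.valence == "positive":
        assert after.total >= before.total
        assert (
            after.subscale_scores[item.subscale_id]
            >= before.subscale_scores[item.subscale_id]
        )
        assert after.section_overalls[item.section] >= before.section_overalls[item.section]
    else:
        assert after.total <= before.total
        assert after.section_overalls[item.section] <= before.section_overalls[item.section]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_permutation_invariance(schema_v2, seed):
    rng = np.random.default_rng(seed)
    audit = random_audit(schema_v2, rng, n_other=3, n_crossings=2)
    perm_rng = np.random.default_rng(seed + 1)

    def shuffled(units):
        units = list(units)
        perm_rng.shuffle(units)
        return tuple(
            UnitAudit(
                u.unit_id, u.unit_kind,
                tuple(sorted(u.responses, key=lambda r: hash(r.item_id))),
            )
            for u in units
        )

    permuted = SchoolAudit(
        school_id=audit.school_id, rater_pair_id=audit.rater_pair_id,
        access_segments=shuffled(audit.access_segments),
        other_segments=shuffled(audit.other_segments),
        crossings=shuffled(audit.crossings),
    )
    a = score_school(audit, schema_v2, validate=False)
    b = score_school(permuted, schema_v2, validate=False)
    assert a.subscale_scores == b.subscale_scores
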