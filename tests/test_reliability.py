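"""ICC(1) estimator, classification, retention rules, stepwise pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from maps_srts import (
    RatingMatrix, apply_retention_rules, classify_reliability, default_schema,
    icc_oneway_single, stepwise_prune,
)

from conftest import icc_oracle


def matrix_of(values):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return RatingMatrix("sub", [f"s{i}" for i in range(n)],
                        [f"r{j}" for j in range(k)], values)


# ---------------------------------------------------------------------------
# point estimate and CI


def test_worked_five_by_two_matrix_matches_oracle():
    values = [[1, 2], [3, 3], [5, 4], [7, 8], [9, 9]]
    res = icc_oneway_single(matrix_of(values))
    est, lo, hi = icc_oracle(values)
    assert res.estimate == pytest.approx(est, abs=1e-12)
    assert res.ci_low == pytest.approx(lo, abs=1e-12)
    assert res.ci_high == pytest.approx(hi, abs=1e-12)
    assert res.ci_low <= res.estimate <= res.ci_high


def test_matches_oracle_on_random_matrices():
    rng = np.random.default_rng(42)
    for _ in range(300):
        n = rng.integers(2, 9)
        k = rng.integers(2, 5)
        values = rng.integers(0, 12, size=(n, k)).astype(float)
        res = icc_oneway_single(matrix_of(values))
        est, lo, hi = icc_oracle(values)
        if est is None:
            assert res.undefined_reason == "no_variability"
        else:
            assert res.estimate == pytest.approx(est, abs=1e-12)
            if lo is not None:
                assert res.ci_low == pytest.approx(lo, abs=1e-12)
                assert res.ci_high == pytest.approx(hi, abs=1e-12)


def test_matches_pingouin_cross_check():
    """Independent library cross-check on a handful of matrices."""
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(7)
    for _ in range(5):
        n, k = 8, 3
        values = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 2
        res = icc_oneway_single(matrix_of(values))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": values.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        )
        row = ref[ref.Type.isin(["ICC1", "ICC(1,1)"])].iloc[0]
        assert res.estimate == pytest.approx(row.ICC, abs=1e-9)
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        lo, hi = row[ci_col]
        assert res.ci_low == pytest.approx(lo, abs=5e-3)  # pingouin rounds
        assert res.ci_high == pytest.approx(hi, abs=5e-3)


def test_perfect_agreement_gives_one():
    res = icc_oneway_single(matrix_of([[1, 1], [4, 4], [9, 9]]))
    assert res.estimate == 1.0
    assert res.ci_low is None and res.ci_high is None


def test_constant_matrix_is_undefined_not_zero():
    res = icc_oneway_single(matrix_of([[3, 3], [3, 3], [3, 3]]))
    assert res.estimate is None
    assert res.undefined_reason == "no_variability"
    assert classify_reliability(res) == "undefined"


def test_rejects_degenerate_designs():
    with pytest.raises(ValueError):
        icc_oneway_single(matrix_of([[1, 2]]))
    with pytest.raises(ValueError):
        icc_oneway_single(matrix_of([[1], [2]]))
    with pytest.raises(ValueError):
        icc_oneway_single(matrix_of([[1, 2], [3, 4]]), alpha=1.5)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    values=arrays(
        float, (5, 2),
        elements=st.integers(0, 20).map(float),
    ),
    shift=st.floats(-50, 50),
    scale=st.floats(0.01, 50),
)
def test_location_scale_invariance(values, shift, scale):
    base = icc_oneway_single(matrix_of(values))
    moved = icc_oneway_single(matrix_of(values * scale + shift))
    if base.estimate is None:
        assert moved.estimate is None
    else:
        assert moved.estimate == pytest.approx(base.estimate, abs=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    values=arrays(float, (6, 2), elements=st.integers(0, 10).map(float)),
)
def test_estimate_bounds_for_two_raters(values):
    res = icc_oneway_single(matrix_of(values))
    if res.estimate is not None:
        assert -1.0 - 1e-12 <= res.estimate <= 1.0 + 1e-12
        assert res.estimate >= -1.0 / (res.k_raters - 1) - 1e-12


def test_negative_estimates_are_legal():
    # strong within-school disagreement relative to between-school spread
    values = [[0, 5], [5, 0], [1, 4], [4, 1]]
    res = icc_oneway_single(matrix_of(values))
    assert res.estimate < 0
    assert res.ci_low <= res.estimate <= res.ci_high


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "estimate,expected",
    [(0.97, "acceptable"), (0.60, "acceptable"), (0.599, "below_threshold"),
     (0.57, "below_threshold"), (-0.22, "below_threshold")],
)
def test_threshold_boundary_inclusive(estimate, expected):
    values = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.5]])
    res = icc_oneway_single(matrix_of(values))
    from dataclasses import replace

    assert classify_reliability(replace(res, estimate=estimate)) == expected


# ---------------------------------------------------------------------------
# retention decision rules


def published_initial_classifications(schema):
    """The initial reliability outcomes reported for the 30 subscales."""
    failing = {
        "sas_positive_buffer": "below_threshold",      # 0.27
        "sas_positive_shade": "undefined",             # n/a
        "sas_positive_bicycle_infrastructure": "undefined",  # n/a
        "sas_overall_positive": "below_threshold",     # 0.19
        "sas_overall": "below_threshold",              # 0.57
        "seg_positive_buffer": "below_threshold",      # -0.22
        "seg_positive_shade": "below_threshold",       # -0.13
        "crs_road_width": "below_threshold",           # 0.25
    }
    return {
        s.subscale_id: failing.get(s.subscale_id, "acceptable")
        for s in schema.non_total_subscales()
    }


def test_retention_rules_reproduce_published_outcome(schema_v1):
    initial = published_initial_classifications(schema_v1)
    assert sum(v == "acceptable" for v in initial.values()) == 22
    revised, decisions = apply_retention_rules(
        initial, schema_v1, revisions={"crs_road_width"}
    )
    by_action = {}
    for d in decisions:
        by_action.setdefault(d.action, []).append(d.subscale_id)
    assert sorted(by_action["remove"]) == [
        "sas_positive_buffer", "sas_positive_shade",
        "seg_positive_buffer", "seg_positive_shade",
    ]
    assert by_action["revise"] == ["crs_road_width"]
    assert sorted(by_action["retain_by_counterpart"]) == [
        "sas_overall", "sas_overall_positive", "sas_positive_bicycle_infrastructure",
    ]
    retained = [d for d in decisions if d.action != "remove"]
    assert len(retained) == 26
    assert len(revised.non_total_subscales()) == 26
    assert len(retained) / len(decisions) == pytest.approx(26 / 30)


def test_retention_all_acceptable_is_identity(schema_v1):
    initial = {s.subscale_id: "acceptable" for s in schema_v1.non_total_subscales()}
    revised, decisions = apply_retention_rules(initial, schema_v1)
    assert all(d.action == "retain" for d in decisions)
    assert {s.subscale_id for s in revised.subscales} == {
        s.subscale_id for s in schema_v1.subscales
    }


def test_removed_leaf_prunes_parent_children(schema_v1):
    initial = published_initial_classifications(schema_v1)
    revised, _ = apply_retention_rules(
        initial, schema_v1, revisions={"crs_road_width"}
    )
    parent = revised.subscale("sas_overall_positive")
    assert set(parent.children) == {
        "sas_positive_streetscape", "sas_positive_sidewalk",
        "sas_positive_bicycle_infrastructure",
    }
    # removed subscales' items remain in the instrument, unscored
    item = revised.item("sas_sidewalk_buffer_present")
    assert item.subscale_id is None and item.valence == "unscored"
    assert len(revised.items) == 90


def test_retention_requires_complete_classifications(schema_v1):
    initial = published_initial_classifications(schema_v1)
    initial.pop("crs_curbs")
    with pytest.raises(ValueError, match="crs_curbs"):
        apply_retention_rules(initial, schema_v1)


# ---------------------------------------------------------------------------
# stepwise pruning


def _builder_from_columns(child_data, rng_noise=None):
    """matrix_builder over synthetic child score columns.

    child_data: dict child_id -> (n, k) array; the parent matrix is the sum
    of the non-excluded children.
    """

    def build(subscale_id, excluded):
        if subscale_id in child_data:
            values = child_data[subscale_id]
        else:
            values = sum(
                v for cid, v in child_data.items() if cid not in excluded
            )
        n, k = values.shape
        return RatingMatrix(subscale_id, [f"s{i}" for i in range(n)],
                            [f"r{j}" for j in range(k)], values)

    return build


def _reliable_column(rng, n, k, noise=0.05):
    truth = rng.normal(0, 3, size=(n, 1))
    return truth + rng.normal(0, noise, size=(n, k))


def test_prune_already_acceptable_parent_is_empty(schema_v1):
    rng = np.random.default_rng(1)
    data = {c: _reliable_column(rng, 10, 2) for c in ("a", "b", "c")}
    sub = schema_v1.subscale("sas_overall_positive")
    from dataclasses import replace

    parent = replace(sub, children=("a", "b", "c"))
    trace = stepwise_prune(_builder_from_columns(data), parent)
    assert trace.steps == ()
    assert trace.final_acceptable


def test_prune_removes_single_noisy_child(schema_v1):
    rng = np.random.default_rng(2)
    data = {
        "good1": _reliable_column(rng, 10, 2),
        "good2": _reliable_column(rng, 10, 2),
        "noisy": rng.normal(0, 30, size=(10, 2)),  # pure rater noise
    }
    from dataclasses import replace

    parent = replace(
        schema_v1.subscale("sas_overall_positive"),
        children=("good1", "good2", "noisy"),
    )
    trace = stepwise_prune(_builder_from_columns(data), parent)
    assert [s.removed_child for s in trace.steps] == ["noisy"]
    assert trace.final_acceptable
    assert trace.initial_icc < 0.60 <= trace.steps[-1].parent_icc


def test_prune_exhausts_to_one_child_when_all_noisy(schema_v1):
    rng = np.random.default_rng(3)
    data = {c: rng.normal(0, 1, size=(8, 2)) for c in ("a", "b", "c", "d")}
    from dataclasses import replace

    parent = replace(
        schema_v1.subscale("sas_overall_positive"), children=("a", "b", "c", "d")
    )
    trace = stepwise_prune(_builder_from_columns(data), parent)
    assert not trace.final_acceptable
    assert len(trace.steps) == 3  # children - 1
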