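import pytest

from maps_srts import (
    ItemResponse, SchoolAudit, UnitAudit, default_schema, generate_grid_network,
)


@pytest.fixture(scope="session")
def schema_v1():
    return default_schema("initial_v1")


@pytest.fixture(scope="session")
def schema_v2():
    return default_schema("final_v2")


@pytest.fixture(scope="session")
def grid_3x3():
    """3x3 block grid, school mid-block in the center, no driveways."""
    return generate_grid_network(3, 3, (1, 1), driveways=0)


def random_unit(schema, section, unit_id, rng):
    responses = tuple(
        ItemResponse(it.item_id, int(rng.choice(it.response_domain.levels)))
        for it in schema.items_for_section(section)
    )
    return UnitAudit(unit_id, section, responses)


def random_audit(schema, rng, school_id="s1", rater_pair_id="p1",
                 n_access=1, n_other=2, n_crossings=2):
    """Uniformly random (domain-valid) audit for property tests."""
    return SchoolAudit(
        school_id=school_id,
        rater_pair_id=rater_pair_id,
        access_segments=tuple(
            random_unit(schema, "school_access_segment", f"a{i}", rng)
            for i in range(n_access)
        ),
        other_segments=tuple(
            random_unit(schema, "other_segment", f"o{i}", rng)
            for i in range(n_other)
        ),
        crossings=tuple(
            random_unit(schema, "crossing", f"c{i}", rng)
            for i in range(n_crossings)
        ),
    )


def icc_oracle(values, alpha=0.05):
    """Brute-force one-way ANOVA ICC(1) in pure Python.

    Independent of the package's estimator: plain loops over floats, mean
    squares from their definitions, Shrout-Fleiss interval endpoints.
    Returns (estimate, ci_low, ci_high) with None entries when undefined.
    """
    from scipy.stats import f as fdist

    rows = [[float(v) for v in row] for row in values]
    n = len(rows)
    k = len(rows[0])
    grand = sum(sum(r) for r in rows) / (n * k)
    row_means = [sum(r) / k for r in rows]
    ssb = sum(k * (m - grand) ** 2 for m in row_means)
    ssw = sum(
        (rows[i][j] - row_means[i]) ** 2 for i in range(n) for j in range(k)
    )
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msb == 0 and msw == 0:
        return None, None, None
    if msw == 0:
        return 1.0, None, None
    est = (msb - msw) / (msb + (k - 1) * msw)
    fobs = msb / msw
    fl = fobs / fdist.ppf(1 - alpha / 2, n - 1, n * (k - 1))
    fu = fobs * fdist.ppf(1 - alpha / 2, n * (k - 1), n - 1)
    return est, (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)


def naive_score_report(audit, schema):
    """Independent tree-walk scoring oracle: leaf-first double loop."""
    scores = {}
    for sub in schema.subscales:
        if schema.is_leaf(sub.subscale_id):
            total = 0.0
            for unit in audit.units_for_section(sub.section):
                vals = unit.response_map()
                if sub.recode == "lanes_dichotomous_gt4":
                    lanes = vals["crs_travel_lanes"] + vals["crs_turn_lanes"]
                    total += 1 if lanes > 4 else 0
                elif sub.recode == "lanes_trichotomous":
                    lanes = vals["crs_travel_lanes"] + vals["crs_turn_lanes"]
                    total += 0 if lanes <= 2 else (1 if lanes <= 4 else 2)
                else:
                    for item_id in sub.children:
                        item = schema.item(item_id)
                        total += item.score_map[vals[item_id]]
            scores[sub.subscale_id] = total
    changed = True
    while changed:
        changed = False
        for sub in schema.subscales:
            sid = sub.subscale_id
            if sid in scores or schema.is_leaf(sid):
                continue
            if all(c in scores for c in sub.children):
                if sub.aggregation == "positive_minus_negative":
                    a, b = sub.children
                    if schema.subscale(a).valence == "positive":
                        scores[sid] = scores[a] - scores[b]
                    else:
                        scores[sid] = scores[b] - scores[a]
                else:
                    scores[sid] = sum(scores[c] for c in sub.children)
                changed = True
    return scores
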