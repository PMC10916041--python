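"""Score one school audit through the full aggregation hierarchy.

Generates a single synthetic two-rater-pair audit and prints the scores
for one rater pair: leaf subscales sum item points across audited units,
each section overall is positive minus negative, and the total sums the
three section overalls.  Higher numbers mean a streetscape more supportive
of walking and bicycling to school.
"""

from maps_srts import (
    AgreementSpec, default_schema, generate_grid_network,
    generate_rater_audits, score_school,
)

schema = default_schema("final_v2")
network = generate_grid_network(3, 3, school_block=(1, 1), driveways=1)
spec = AgreementSpec(target_icc=0.9, n_schools=1, k_rater_pairs=2, seed=11)
audit = generate_rater_audits(schema, network, spec)[0]

report = score_school(audit, schema)
print(f"school {report.school_id}, rater pair {report.rater_pair_id}\n")
for section in ("school_access_segment", "other_segment", "crossing"):
    overall_id = schema.section_overall_id(section)
    print(f"{section}:")
    for sub in schema.non_total_subscales():
        if sub.section == section and schema.is_leaf(sub.subscale_id):
            print(f"  {sub.subscale_id:38s} {report.subscale_scores[sub.subscale_id]:6.0f}")
    print(f"  {'section overall (pos - neg)':38s} {report.section_overalls[section]:6.0f}")
print(f"\ntotal score: {report.total:.0f}")
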