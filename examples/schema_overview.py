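"""Inspect the shipped instrument: item counts and version differences.

The audit instrument has 90 items in three sections (school access
segments, other segments near the school, crossings).  The initial scoring
schema aggregates them into 30 subscales; the final schema keeps 26 after
the reliability-driven removals plus one recode.
"""

from maps_srts import count_items, default_schema, diff_versions

v1 = default_schema("initial_v1")
v2 = default_schema("final_v2")

print("items per section (final schema):")
for section in ("school_access_segment", "other_segment", "crossing"):
    print(f"  {section:22s} {count_items(v2, section)}")
print(f"non-total subscales: initial={len(v1.non_total_subscales())}, "
      f"final={len(v2.non_total_subscales())}")

print("\nchanges from initial to final schema:")
for change in diff_versions(v1, v2):
    print(f"  {change.kind:8s} {change.subscale_id}")
print("(removed: unreliable buffer/shade subscales in both segment sections;"
      "\n revised: road width, recoded to a >4-total-lanes dichotomy)")
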