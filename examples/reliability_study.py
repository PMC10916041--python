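"""End-to-end inter-rater reliability study on synthetic audits.

Simulates 36 schools audited by two independent rater pairs, with the
buffer and shade subscales in both segment sections engineered to have
near-zero agreement while every other subscale agrees strongly.  The
pipeline scores all audits, computes a one-way random-effects
single-measure ICC per subscale, classifies each against the 0.60
acceptability threshold, and applies the retention decision rules: the
four unreliable leaves are removed, subscales with a reliable same-content
counterpart are retained, and 26 of 30 subscales survive.
"""

from maps_srts import (
    AgreementSpec, default_schema, generate_grid_network,
    generate_rater_audits, run_full_reliability_study,
)

schema = default_schema("initial_v1")
network = generate_grid_network(3, 3, school_block=(1, 1), driveways=1)
targets = {
    "default": 0.95,
    "sas_positive_buffer": 0.05, "sas_positive_shade": 0.05,
    "seg_positive_buffer": 0.05, "seg_positive_shade": 0.05,
}
spec = AgreementSpec(target_icc=targets, n_schools=36, k_rater_pairs=2, seed=2019)
audits = generate_rater_audits(schema, network, spec)

result = run_full_reliability_study(audits, schema)
print(result.summary(), "\n")
print("decisions other than plain retention:")
for d in result.decisions:
    if d.action != "retain" or d.rationale != "acceptable":
        print(f"  {d.subscale_id:28s} {d.action:22s} ({d.rationale})")
print("\nICC per removed subscale:")
removed = {d.subscale_id for d in result.decisions if d.action == "remove"}
for _, row in result.icc[result.icc.subscale_id.isin(removed)].iterrows():
    print(f"  {row.subscale_id:28s} ICC={row.icc: .2f} "
          f"[{row.ci_low: .2f}, {row.ci_high: .2f}]")
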