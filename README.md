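# maps-srts

Toolkit for the **MAPS-SRTS** instrument — the Micro-scale Audit of
Pedestrian Streetscapes adapted for Safe Routes to School.  It is aimed at
researchers and practitioners who audit the street environment around
schools to assess how supportive it is of children walking and bicycling
to school, and who need reproducible scoring and inter-rater reliability
analysis for those audits.

The package provides:

- **Scoring schema registry** — a machine-readable encoding of the 90-item
  instrument (33 school-access-segment, 30 other-segment, and 27 crossing
  items) and its hierarchical aggregation tree, in two versions: the
  initial schema with 30 subscales and the final schema with 26 subscales
  plus a recoded road-width subscale.
- **Audit data model and I/O** — strictly validated school audits in long
  CSV or nested JSON, one record per (school, rater pair, unit, item).
- **Scoring engine** — item points are summed into subscales across all
  audited units, each section overall is *positive − negative*, and the
  total is the sum of the three section overalls:
  `Total = Σ_section (Overall⁺_section − Overall⁻_section)`.
- **Reliability engine** — one-way random-effects single-measure
  intraclass correlation, ICC(1) = (MS_B − MS_W) / (MS_B + (k−1)·MS_W),
  with the exact F-based 95% confidence interval, the 0.60 acceptability
  threshold, counterpart-aware subscale retention rules, and stepwise item
  pruning.
- **Route sampler** — the nearest-neighbor observation route on a street
  network: the school access segment(s), every crossing connecting to
  them (including school driveways), and every incident street segment on
  one side.
- **Synthetic fixtures** — street-grid networks and paired-rater audit
  datasets with per-subscale agreement calibrated to a target ICC, so the
  whole pipeline is testable without field data.

## Worked example

`examples/reliability_study.py` simulates 36 schools audited by two
independent rater pairs, with the buffer and shade subscales in both
segment sections engineered to have near-zero agreement, then runs the
full pipeline:

```
subscales tested: 30
removed for low reliability: 4
retained in the final schema: 26
revised (recoded): 0
total-score ICC: 0.96

decisions other than plain retention:
  sas_positive_buffer          remove                 (low_icc_no_counterpart)
  sas_positive_shade           remove                 (low_icc_no_counterpart)
  seg_positive_buffer          remove                 (low_icc_no_counterpart)
  seg_positive_shade           remove                 (low_icc_no_counterpart)
```

The four engineered low-agreement subscales fall below the 0.60 threshold
in both sections (so neither has a reliable same-content counterpart) and
are removed; the remaining 26 subscales — 86.7% of the original 30 — are
retained, and the total score's ICC stays high because it aggregates many
reliable components.

The other example scripts are narrower: `schema_overview.py` prints the
instrument structure and the initial→final schema diff,
`observation_route.py` builds a route on a toy grid (1 access segment,
2 intersection + 2 driveway crossings, 6 other segments), and
`score_one_school.py` scores a single audit through the hierarchy.

There is also a CLI mirroring the library
(`maps-srts schema|audits|score|reliability|route|simulate|study`), e.g.

```bash
maps-srts simulate --schools 36 --icc 0.8 --seed 42 --out audits.csv
maps-srts study audits.csv --version initial_v1 --out-dir report/
```

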