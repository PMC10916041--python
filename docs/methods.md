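# Methods

## The instrument and its scoring model

MAPS-SRTS is a direct-observation audit of the micro-scale street
environment around a school.  Raters walk a defined observation route and
answer 90 items across three unit types: the *school access segment*
(the street fronting the main entrance; 33 items), *other segments* near
the school (30 items), and *crossings* (27 items).  Items are binary
presence/absence unless noted; the bicycle-infrastructure item is a
3-level ordinal (none / marked lane / marked lane with physical barrier),
shade coverage is a 4-level ordinal band (none / 1–25% / 26–75% /
76–100%), and the two road-width items are lane counts (0–10).

Scoring is hierarchical.  Item points (default: 1 per present binary
feature, the level index for ordinals) are summed within a unit, summed
across all audited units of the section, and grouped into subscales with
positive or negative valence.  Each section's overall score is its
positive overall minus its negative overall; the total is the sum of the
three section overalls, so a higher total means a streetscape more
supportive of walking and bicycling to school.  Summation (not averaging)
across units is deliberate: a school with nine audited segments
accumulates nine segments' worth of amenity points, which matches the
score magnitudes such audits report and makes scores additive under route
growth.  The consequences are documented rather than hidden: totals are
not comparable between schools with very different route sizes unless the
caller normalizes.

Two schema versions ship.  `initial_v1` has 30 non-total subscales
(11 school-access, 11 other-segment, 8 crossing).  `final_v2` has 26:
the positive buffer and positive shade subscales are dropped from both
segment sections (their items remain in the instrument as unscored, so
version-1 data re-scores under version 2 without loss), and road width is
recoded.  Because Table-style per-subscale item counts do not exhaust the
per-section item totals, the remainder items are carried as unscored in
both versions.  Each school-access subscale names its same-content
other-segment subscale as a counterpart, which the retention rules use.

**Road width.**  The final subscale scores one negative point per
crossing when travel + turn lanes exceed 4 (roads wider than 4 lanes
being a pedestrian-crash risk factor).  The initial version trichotomized
the lane total; the cutpoints of that historical trichotomy are not
published, so this package uses ≤2 / 3–4 / ≥5, which nests the published
dichotomy boundary.  Only the dichotomy feeds the final scoring.

## Inter-rater reliability

Reliability uses the one-way random-effects single-measure ICC, the
estimator appropriate when each school is rated by rating sources that
are not crossed with schools (here, two-person rater pairs treated as a
single source).  With n schools and k raters, from the one-way ANOVA mean
squares MS_B (between schools) and MS_W (within schools):

    ICC(1) = (MS_B − MS_W) / (MS_B + (k − 1) MS_W)

The 95% interval is the exact F-based construction: F = MS_B/MS_W on
(n−1, n(k−1)) degrees of freedom; each endpoint F* maps through
(F* − 1)/(F* + k − 1).  Negative estimates are legal (floor −1/(k−1)) and
arise when rater disagreement swamps between-school spread.  Degenerate
cases are explicit rather than silent: a constant matrix returns an
*undefined* result with reason `no_variability` (the field-report "N/A"),
and perfect agreement with real between-school variance returns exactly
1.0 with no finite interval.  α defaults to 0.05 and is overridable.

Classification uses a threshold of 0.60, boundary inclusive (an estimate
of exactly 0.60 is acceptable).

**Retention decision rules.**  Given a classification for every non-total
subscale, plus a set of subscales with registered recodes (revisions):

1. a revised subscale is kept with action `revise`;
2. an acceptable subscale is retained;
3. a failing subscale whose counterpart (same item content in another
   section) is acceptable is retained (`retain_by_counterpart`) — low
   variability on the single access segment is not treated as evidence
   against item content that is demonstrably reliable across many
   segments;
4. a failing leaf with no reliable counterpart is removed, its items
   downgraded to unscored;
5. a failing composite parent is never removed outright: its child list
   is re-derived after the leaf decisions (parents typically recover once
   their noisy children are gone).  This required one rationale label
   (`composite_rederived`) beyond the four obvious ones.

"Theoretical relevance", which practitioners also weigh, is not
computable; it is operationalized solely through the counterpart and
revision mechanisms above, and that narrowing is a known limitation.

Stepwise pruning (`stepwise_prune`) supports diagnosing a failing parent:
children are removed one at a time in order of their own ICC (undefined
sorts worst; ties break on child order), re-estimating the parent ICC
after each removal, until the parent is acceptable or one child remains.

## Observation route sampling

The route is built topologically on a planar node/edge street graph.
Access segments are either declared explicitly (`access_edge_ids`,
validated for adjacency — frontage is confirmed manually in practice) or
inferred as the edge(s) nearest the entrance point; distance ties are
resolved in favor of edges the entrance lies *alongside* (perpendicular
foot within the edge span), so an intersection facing the entrance splits
the frontage into two access segments while the cross street arriving at
that intersection is not mistaken for frontage.

Crossings are the access-segment endpoints where at least two edges meet
(a dead end is not a crossing) plus the school's own driveway nodes on an
access segment; driveways are point annotations on their host edge and
never split it.  Other segments are all edges incident to an intersection
crossing except access segments — the one-hop nearest-neighbor rule — each
taken on exactly one side of the street.  The default side is the side
facing the school entrance (sign of the cross product relative to the
edge direction between sorted endpoint ids; collinear points default to
"left"); field teams can override sides downstream since the side label
is carried in the output.  Mid-block driveways on non-access segments are
not treated as crossings.  All outputs are id-sorted, making routes
invariant to node/edge insertion order.

## Synthetic data generator

The generator emulates the study design the reliability machinery
expects: n schools (default 36, with a 5-school two-pair subsample being
the typical reliability design), k = 2 rater pairs, one shared
observation route.  Every scored response is built from latent Bernoulli
components — one per binary item, L−1 for an L-level ordinal (a
binomial), offset + components for lane counts — with component presence
probability `sigmoid(mu_t + b_i)`, where `b_i ~ N(0, sd_b²)` is the
school effect (default sd_b = 1 on the logit scale) and the per-component
intercepts mu_t ~ N(0, 0.5²) are drawn once per dataset.  The realized
components are the school's true streetscape, shared by all rater pairs;
each pair observes them through independent symmetric flips with
per-subscale rate q.

q is calibrated by bisection against the closed-form population ICC of
the subscale point sum,

    ICC(q) = B(q) / (B(q) + W(q)),
    B(q) = (1 − 2q)² (U² Var_b S + U E_b V),    W(q) = U m q(1 − q),

with S(b), V(b) the conditional mean and variance of one unit's component
sum (Gauss–Hermite quadrature over b), U the section's unit count and m
the subscale's component count.  This mapping is exact for sums of
Bernoulli components, so audit-level ICC estimates recover the target
within sampling error (verified at ±0.05, n = 200); the nonlinear
road-width recode inherits its items' flip rate and is only approximately
calibrated.  A separate continuous latent layer implements the
variance-component definition directly (rater noise variance
sd_b²(1 − icc)/icc) and converges to the target within ±0.02 at
n = 1000.  Infeasible targets (outside (0, 1), or nonpositive sd_b) raise
with the legal bounds.  Identical spec and seed give byte-identical
serialized datasets.

What the generator does *not* emulate: real item prevalences and
inter-item correlations, spatially realistic street geometry, systematic
(non-symmetric) rater bias, or the published study's actual score
distributions — its raw data are not public.  Passing tests therefore
demonstrate correctness of the scoring/reliability machinery under a
controlled agreement model, not distributional fidelity to any field
sample.

## Numerical and design choices

- ICC mean squares are computed directly from their definitional sums of
  squares in float64; the test suite pins the estimator to a pure-Python
  from-first-principles oracle at 1e-12 and cross-checks against an
  independent library implementation.
- Undefined reliability is a typed result, never NaN or 0, so decision
  rules must confront it explicitly.
- Validation is total: schema loading and audit loading either return a
  fully valid object or raise an error listing every violation; missing
  item responses are rejected, never zero-filled (absence is expressed as
  an explicit 0-scoring "not present" response).
- Simulation sizes in tests and the acceptance script (500 replicates for
  recovery/coverage, 36-school end-to-end fixtures, 200-school
  calibration checks) were chosen to make sampling error small relative
  to the tolerances being checked while keeping a full run in seconds.
- The end-to-end fixture engineers buffer/shade agreement at ICC 0.05 and
  everything else at 0.95; at n = 36 the estimator's sampling error makes
  misclassification of any subscale vanishingly unlikely, so the
  4-removed / 26-retained outcome is stable across seeds.

## Known limitations

- The shipped dictionary reconstructs the instrument's structure (counts,
  tree, valences, response domains) exactly, but most item wording is
  placeholder text; studies wanting the verbatim field instrument should
  load their own dictionary JSON/CSV.
- Unit identity across rater pairs is matched by `unit_id` string
  equality; no spatial matching is attempted.
- Route side selection is a reproducible default, not a field protocol;
  curved or multi-edge frontage must be declared, not inferred.
- Two-way ICC models, chance-corrected categorical agreement, internal
  consistency, and validity against travel behavior are out of scope.
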