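"""Inter-rater reliability: one-way random-effects single-measure ICC.

The reliability model treats each school as a random subject rated once by
each of k interchangeable rating sources (two-person rater pairs).  From
the one-way ANOVA decomposition with between-subject mean square MSB and
within-subject mean square MSW,

    ICC(1) = (MSB - MSW) / (MSB + (k - 1) * MSW),

with the exact F-based confidence interval of Shrout & Fleiss: F = MSB/MSW
on (n-1, n(k-1)) degrees of freedom, and each interval endpoint mapped
through (F* - 1) / (F* + k - 1).

A subscale with no variability at all (every cell identical) has no
estimable reliability and is reported as an explicit *undefined* result,
mirroring "N/A" entries in field studies; it is never silently coerced to
0 or NaN.  Perfect agreement with real between-school variance yields an
estimate of exactly 1.0 with no finite confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Callable, Mapping, Optional

import numpy as np
from scipy import stats

from .audits import RatingMatrix
from .schema import ScoringSchema, SubscaleDef

ACCEPTABILITY_THRESHOLD = 0.60  # "0.60 or higher" deemed acceptable


@dataclass(frozen=True)
class ICCResult:
    subscale_id: str
    estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_subjects: int
    k_raters: int
    msb: float
    msw: float
    undefined_reason: Optional[str] = None  # 'no_variability' when undefined

    @property
    def defined(self) -> bool:
        return self.estimate is not None


@dataclass(frozen=True)
class DecisionOutcome:
    subscale_id: str
    action: str  # retain | remove | revise | retain_by_counterpart
    rationale: str


def icc_oneway_single(
    matrix: RatingMatrix, alpha: float = 0.05
) -> ICCResult:
    """ICC(1) point estimate and exact F-based (1 - alpha) CI for one matrix."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    y = matrix.values
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 subjects and k >= 2 raters, got {n} x {k}")

    subject_means = y.mean(axis=1)
    grand_mean = y.mean()
    msb = k * float(np.sum((subject_means - grand_mean) ** 2)) / (n - 1)
    msw = float(np.sum((y - subject_means[:, None]) ** 2)) / (n * (k - 1))

    if msb == 0.0 and msw == 0.0:
        return ICCResult(
            matrix.subscale_id, None, None, None, n, k, msb, msw,
            undefined_reason="no_variability",
        )

    estimate = (msb - msw) / (msb + (k - 1) * msw)

    if msw == 0.0:
        # Perfect within-subject agreement: estimate is exactly 1, the F
        # statistic is infinite and the interval degenerates.
        return ICCResult(matrix.subscale_id, 1.0, None, None, n, k, msb, msw)

    df1, df2 = n - 1, n * (k - 1)
    f_obs = msb / msw
    f_upper_tail = stats.f.ppf(1 - alpha / 2, df1, df2)
    f_lower_tail = stats.f.ppf(1 - alpha / 2, df2, df1)
    fl = f_obs / f_upper_tail
    fu = f_obs * f_lower_tail
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return ICCResult(matrix.subscale_id, estimate, ci_low, ci_high, n, k, msb, msw)


def classify_reliability(
    result: ICCResult, threshold: float = ACCEPTABILITY_THRESHOLD
) -> str:
    """'acceptable' (estimate >= threshold), 'below_threshold', or 'undefined'."""
    if not result.defined:
        return "undefined"
    return "acceptable" if result.estimate >= threshold else "below_threshold"


# ---------------------------------------------------------------------------
# retention decision rules


def apply_retention_rules(
    initial: Mapping,
    schema: ScoringSchema,
    revisions: Optional[set] = None,
) -> tuple:
    """Decide each subscale's fate from its reliability classification.

    ``initial`` maps every non-total subscale_id to its classification
    ('acceptable' / 'below_threshold' / 'undefined').  A subscale is
    removed iff it fails (below threshold or undefined), has no
    same-content counterpart in another section with acceptable
    reliability, is not flagged as revised (recoded), and is a leaf;
    composite parents are never removed outright — their child lists are
    re-derived after the leaf decisions.

    Returns ``(revised_schema, decisions)``.
    """
    revisions = revisions or set()
    decisions: list[DecisionOutcome] = []
    removed: set[str] = set()
    for sub in schema.non_total_subscales():
        sid = sub.subscale_id
        if sid not in initial:
            raise ValueError(f"no reliability classification for subscale {sid}")
        cls = initial[sid]
        if sid in revisions:
            decisions.append(DecisionOutcome(sid, "revise", "recoded"))
            continue
        if cls == "acceptable":
            decisions.append(DecisionOutcome(sid, "retain", "acceptable"))
            continue
        counterpart = sub.counterpart_id
        if counterpart is not None and initial.get(counterpart) == "acceptable":
            decisions.append(
                DecisionOutcome(sid, "retain_by_counterpart", "low_icc_counterpart_reliable")
            )
            continue
        if schema.is_leaf(sid):
            decisions.append(DecisionOutcome(sid, "remove", "low_icc_no_counterpart"))
            removed.add(sid)
        else:
            decisions.append(DecisionOutcome(sid, "retain", "composite_rederived"))

    revised = _rebuild_without(schema, removed, revisions)
    return revised, decisions


def _rebuild_without(
    schema: ScoringSchema, removed: set, revisions: set
) -> ScoringSchema:
    """Drop removed subscales, unscore their items, prune parents' children."""
    from .schema import ScoringSchema as _Schema

    new_subscales = []
    for sub in schema.subscales:
        if sub.subscale_id in removed:
            continue
        children = tuple(c for c in sub.children if c not in removed)
        status = "revised" if sub.subscale_id in revisions else sub.status
        new_subscales.append(
            _dc_replace(sub, children=children, status=status)
        )
    new_items = []
    for it in schema.items:
        if it.subscale_id in removed:
            new_items.append(
                _dc_replace(it, subscale_id=None, valence="unscored")
            )
        else:
            new_items.append(it)
    out = _Schema(
        version="final_v2" if schema.version == "initial_v1" else schema.version,
        items=new_items,
        subscales=new_subscales,
        total_id=schema.total_id,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# stepwise pruning


@dataclass(frozen=True)
class PruneStep:
    removed_child: str
    parent_icc: Optional[float]


@dataclass(frozen=True)
class PruneTrace:
    subscale_id: str
    initial_icc: Optional[float]
    steps: tuple  # of PruneStep
    final_acceptable: bool


def stepwise_prune(
    matrix_builder: Callable[[str, frozenset], RatingMatrix],
    subscale: SubscaleDef,
    threshold: float = ACCEPTABILITY_THRESHOLD,
    alpha: float = 0.05,
) -> PruneTrace:
    """Remove the least reliable child at a time until the parent is acceptable.

    ``matrix_builder(subscale_id, excluded_children)`` must return the
    rating matrix for that subscale computed with the given children
    excluded from aggregation (the exclusion set is empty for child
    matrices).  Children whose own ICC is undefined sort below any defined
    estimate; ties break on child order within the subscale.
    """
    if len(subscale.children) < 2:
        raise ValueError(f"{subscale.subscale_id} has fewer than 2 children")

    def parent_icc(excluded: frozenset) -> Optional[float]:
        res = icc_oneway_single(
            matrix_builder(subscale.subscale_id, excluded), alpha
        )
        return res.estimate

    def acceptable(est: Optional[float]) -> bool:
        return est is not None and est >= threshold

    excluded: frozenset = frozenset()
    initial = current = parent_icc(excluded)
    steps: list[PruneStep] = []
    if acceptable(current):
        return PruneTrace(subscale.subscale_id, current, (), True)

    remaining = list(subscale.children)
    while len(remaining) > 1 and not acceptable(current):
        child_iccs = []
        for idx, child in enumerate(remaining):
            res = icc_oneway_single(matrix_builder(child, frozenset()), alpha)
            key = res.estimate if res.defined else -np.inf
            child_iccs.append((key, idx, child))
        _, _, worst = min(child_iccs)
        remaining.remove(worst)
        excluded = excluded | {worst}
        current = parent_icc(excluded)
        steps.append(PruneStep(worst, current))

    return PruneTrace(
        subscale.subscale_id, initial, tuple(steps), acceptable(current)
    )
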