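"""Synthetic street networks and paired-rater audit data.

The generator emulates the reliability design of a school audit study:
each school is walked independently by k rater pairs (k = 2 by default)
over the same observation route, and agreement between pairs is
controllable per subscale.

Model.  Each school carries a latent supportiveness ``b_i ~ N(0, sd_b^2)``
on the logit scale.  Every scored response is built from latent Bernoulli
components (a binary item is one component, an L-level ordinal item is
L - 1 components, lane counts are an offset plus components) with
per-component presence probability ``sigmoid(mu_t + b_i)``.  The realized
component values are the school's true streetscape, shared by all rater
pairs; each pair observes every component through an independent symmetric
flip channel with subscale-specific flip rate q.  q is calibrated by
bisection so that the population ICC of the subscale's item-point sum
matches ``target_icc``:

    ICC(q) = B(q) / (B(q) + W(q)),
    B(q) = (1 - 2q)^2 * (U^2 * Var_b S + U * E_b V),   W(q) = U * m * q(1 - q)

with S(b), V(b) the conditional mean and variance of a unit's component sum
and U the number of audited units in the section (moments by Gauss-Hermite
quadrature).  The continuous latent layer used for calibration checks is
exact by construction: rater noise variance sd_b^2 * (1 - icc) / icc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .audits import ItemResponse, SchoolAudit, UnitAudit
from .routes import Edge, Node, School, StreetNetwork, select_route
from .schema import ScoringSchema

_BLOCK = 100.0  # grid spacing in planar units (~ a short city block, m)


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class AgreementSpec:
    """Target agreement and design shape for synthetic audits."""

    target_icc: Union[float, Mapping] = 0.8  # scalar or subscale_id -> icc
    n_schools: int = 36
    k_rater_pairs: int = 2
    between_school_sd: float = 1.0
    seed: int = 0

    def resolve_target(self, subscale_id: str) -> float:
        if isinstance(self.target_icc, Mapping):
            default = self.target_icc.get("default", 0.8)
            return float(self.target_icc.get(subscale_id, default))
        return float(self.target_icc)


# ---------------------------------------------------------------------------
# street networks


def generate_grid_network(
    blocks_x: int,
    blocks_y: int,
    school_block: tuple,
    driveways: int = 0,
    seed: int = 0,
) -> StreetNetwork:
    """Rectangular street grid with the school placed mid-block.

    ``school_block`` is the (bx, by) block index; the school fronts the
    block's south edge, with ``driveways`` school driveway annotations on
    that access edge.  Fully deterministic; ``seed`` is accepted for
    interface symmetry with the audit generator.
    """
    if blocks_x < 1 or blocks_y < 1:
        raise ValueError("grid must have at least 1x1 blocks")
    bx, by = school_block
    if not (0 <= bx < blocks_x and 0 <= by < blocks_y):
        raise ValueError(f"school_block {school_block} outside {blocks_x}x{blocks_y} grid")

    nodes: dict = {}
    edges: dict = {}
    for ix in range(blocks_x + 1):
        for iy in range(blocks_y + 1):
            nid = f"n{ix}_{iy}"
            nodes[nid] = Node(nid, ix * _BLOCK, iy * _BLOCK, "intersection")
    for ix in range(blocks_x):
        for iy in range(blocks_y + 1):
            eid = f"eh{ix}_{iy}"
            edges[eid] = Edge(eid, f"n{ix}_{iy}", f"n{ix + 1}_{iy}", f"street_y{iy}")
    for ix in range(blocks_x + 1):
        for iy in range(blocks_y):
            eid = f"ev{ix}_{iy}"
            edges[eid] = Edge(eid, f"n{ix}_{iy}", f"n{ix}_{iy + 1}", f"avenue_x{ix}")

    access_edge = f"eh{bx}_{by}"
    driveway_ids = []
    for d in range(driveways):
        did = f"drv{d}"
        t = (d + 1) / (driveways + 1)
        nodes[did] = Node(
            did, (bx + t) * _BLOCK, by * _BLOCK, "driveway", host_edge=access_edge
        )
        driveway_ids.append(did)

    school = School(
        entrance_point=((bx + 0.5) * _BLOCK, by * _BLOCK + 0.1 * _BLOCK),
        access_edge_ids=None,
        driveway_nodes=tuple(driveway_ids),
    )
    return StreetNetwork(nodes, edges, school)


# ---------------------------------------------------------------------------
# latent component layout per leaf subscale


@dataclass(frozen=True)
class _ComponentItem:
    item_id: str
    n_components: int
    offset: int  # constant added to the component sum (lane-count floors)


#: component structure for non-binary default-instrument items
_SPECIAL_COMPONENTS = {
    "bicycle_infrastructure": (2, 0),  # ordinal 0..2
    "sidewalk_shade_coverage": (3, 0),  # ordinal 0..3
    "travel_lanes": (4, 1),  # counts 1..5
    "turn_lanes": (2, 0),  # counts 0..2
}


def _component_items(schema: ScoringSchema, section: str) -> list:
    out = []
    for it in schema.items_for_section(section):
        stem = it.item_id.split("_", 1)[1]
        n_comp, offset = _SPECIAL_COMPONENTS.get(stem, (1, 0))
        n_levels = len(it.response_domain.levels)
        if it.response_domain.kind in ("ordinal", "count"):
            n_comp = min(n_comp, n_levels - 1)
        out.append(_ComponentItem(it.item_id, n_comp, offset))
    return out


# ---------------------------------------------------------------------------
# agreement calibration


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(61)


def _subscale_moments(mus: np.ndarray, sd_b: float) -> tuple:
    """(Var_b S, E_b V) for one unit's component sum, by Gauss-Hermite."""
    b = np.sqrt(2.0) * sd_b * _GH_NODES  # quadrature points of N(0, sd_b^2)
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    p = expit(mus[None, :] + b[:, None])  # (nodes, components)
    s = p.sum(axis=1)
    v = (p * (1 - p)).sum(axis=1)
    es = float(w @ s)
    return float(w @ s**2 - es**2), float(w @ v)


def population_icc(mus: np.ndarray, sd_b: float, n_units: int, q: float) -> float:
    """Population ICC of a subscale's point sum at flip rate q."""
    var_s, e_v = _subscale_moments(mus, sd_b)
    u, m = n_units, len(mus)
    between = (1 - 2 * q) ** 2 * (u**2 * var_s + u * e_v)
    within = u * m * q * (1 - q)  # independent flip channel per rating
    return between / (between + within) if between + within > 0 else 0.0


def calibrate_flip_rate(
    mus: np.ndarray, sd_b: float, n_units: int, target_icc: float
) -> float:
    """Solve population_icc(q) = target_icc for q in [0, 0.5) by bisection."""
    if not 0.0 < target_icc < 1.0:
        raise CalibrationError(
            f"target_icc {target_icc} infeasible; choose a value strictly "
            f"inside (0, 1)"
        )
    if sd_b <= 0:
        raise CalibrationError("between_school_sd must be positive")
    if len(mus) == 0 or n_units == 0:
        return 0.0

    def f(q: float) -> float:
        return population_icc(mus, sd_b, n_units, q) - target_icc

    hi = 0.5 - 1e-9
    if f(hi) > 0:  # even maximal noise stays above target
        return hi
    return float(brentq(f, 0.0, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# audit generation


def generate_latent_scores(
    spec: AgreementSpec, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Continuous latent subscale scores under the exact variance-component
    definition: (n_schools, k) matrix with population ICC = target_icc."""
    target = (
        spec.resolve_target("default")
        if isinstance(spec.target_icc, Mapping)
        else float(spec.target_icc)
    )
    if not 0.0 < target < 1.0:
        raise CalibrationError("target_icc must lie strictly inside (0, 1)")
    rng = rng or np.random.default_rng(spec.seed)
    sd_b = spec.between_school_sd
    sd_w = sd_b * np.sqrt((1 - target) / target)
    true = rng.normal(0.0, sd_b, size=(spec.n_schools, 1))
    noise = rng.normal(0.0, sd_w, size=(spec.n_schools, spec.k_rater_pairs))
    return true + noise


def generate_rater_audits(
    schema: ScoringSchema,
    network: StreetNetwork,
    spec: AgreementSpec,
) -> list:
    """Synthesize complete k-rater-pair audits for n schools on one route.

    Every school is audited over the route implied by ``network``; all
    rater pairs share each school's realized streetscape and differ only
    through the calibrated flip channel.  Deterministic given ``spec.seed``.
    """
    if spec.n_schools < 1 or spec.k_rater_pairs < 1:
        raise ValueError("need at least one school and one rater pair")
    rng = np.random.default_rng(spec.seed)
    route = select_route(network)
    units_by_section = {
        "school_access_segment": [f"acc_{e}" for e in route.access_segments],
        "other_segment": [f"oth_{e}" for e, _ in route.other_segments],
        "crossing": [f"crs_{n}" for n in route.crossings],
    }

    # Per-component intercepts, drawn once so the item mix is fixed across
    # schools; mild spread keeps marginal prevalences away from 0/1.
    comp_items = {sec: _component_items(schema, sec) for sec in units_by_section}
    mus: dict = {}
    for sec, items in comp_items.items():
        for ci in items:
            mus[ci.item_id] = rng.normal(0.0, 0.5, size=ci.n_components)

    # Flip rate per leaf subscale; unscored items use a fixed nominal rate.
    q_by_item: dict = {}
    for sub in schema.leaf_subscales():
        n_units = len(units_by_section[sub.section])
        sub_mus = np.concatenate(
            [mus[item_id] for item_id in sub.children]
        ) if sub.children else np.array([])
        q = calibrate_flip_rate(
            sub_mus, spec.between_school_sd, max(n_units, 1),
            spec.resolve_target(sub.subscale_id),
        )
        for item_id in sub.children:
            q_by_item[item_id] = q
    q_unscored = 0.1

    audits: list[SchoolAudit] = []
    for i in range(spec.n_schools):
        b_i = rng.normal(0.0, spec.between_school_sd)
        # true component values per unit/item, shared across rater pairs
        truth: dict = {}
        for sec, unit_ids in units_by_section.items():
            for unit_id in unit_ids:
                for ci in comp_items[sec]:
                    p = expit(mus[ci.item_id] + b_i)
                    truth[(unit_id, ci.item_id)] = rng.random(ci.n_components) < p
        for j in range(spec.k_rater_pairs):
            sections: dict = {sec: [] for sec in units_by_section}
            for sec, unit_ids in units_by_section.items():
                for unit_id in unit_ids:
                    responses = []
                    for ci in comp_items[sec]:
                        q = q_by_item.get(ci.item_id, q_unscored)
                        flips = rng.random(ci.n_components) < q
                        observed = truth[(unit_id, ci.item_id)] ^ flips
                        responses.append(
                            ItemResponse(ci.item_id, int(observed.sum()) + ci.offset)
                        )
                    sections[sec].append(
                        UnitAudit(unit_id, sec, tuple(responses))
                    )
            audits.append(
                SchoolAudit(
                    school_id=f"school_{i:04d}",
                    rater_pair_id=f"pair_{j}",
                    access_segments=tuple(sections["school_access_segment"]),
                    other_segments=tuple(sections["other_segment"]),
                    crossings=tuple(sections["crossing"]),
                )
            )
    return audits
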