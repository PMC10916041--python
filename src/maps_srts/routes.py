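"""Observation-route construction on a school street network.

The audit route anchors on the *school access segment(s)* — the street
edge(s) fronting the main school entrance — and extends by nearest-neighbor
spatial sampling: (1) take every crossing that connects to a school access
segment; (2) from each of those crossings, take every incident street
segment on one side of the street.  School driveways on the access segment
count as crossings but never split the segment, so they are represented as
point annotations on an edge rather than graph nodes with degree.

Coordinates are planar (x, y); selection is purely topological, so any
consistent local projection works.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import networkx as nx
import pandas as pd


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class Node:
    node_id: str
    x: float
    y: float
    kind: str  # 'intersection' | 'driveway'
    host_edge: Optional[str] = None  # required for driveway nodes


@dataclass(frozen=True)
class Edge:
    edge_id: str
    node_a: str
    node_b: str
    street_name: str = ""


@dataclass(frozen=True)
class School:
    entrance_node: Optional[str] = None
    entrance_point: Optional[Tuple[float, float]] = None
    access_edge_ids: Optional[tuple] = None
    driveway_nodes: tuple = ()  # school entrance/exit driveways


@dataclass
class StreetNetwork:
    nodes: dict  # node_id -> Node
    edges: dict  # edge_id -> Edge
    school: School

    def __post_init__(self):
        self.validate()
        self._graph = nx.MultiGraph()
        for n_id, node in self.nodes.items():
            if node.kind == "intersection":
                self._graph.add_node(n_id)
        for e_id, e in self.edges.items():
            self._graph.add_edge(e.node_a, e.node_b, key=e_id)

    def validate(self) -> None:
        errors = []
        for e in self.edges.values():
            for endpoint in (e.node_a, e.node_b):
                if endpoint not in self.nodes:
                    errors.append(f"edge {e.edge_id}: unknown endpoint {endpoint}")
                elif self.nodes[endpoint].kind != "intersection":
                    errors.append(
                        f"edge {e.edge_id}: endpoint {endpoint} is not an intersection"
                    )
        for node in self.nodes.values():
            if node.kind == "driveway":
                if node.host_edge is None or node.host_edge not in self.edges:
                    errors.append(
                        f"driveway {node.node_id}: must lie on exactly one known edge"
                    )
        sc = self.school
        if sc.entrance_node is None and sc.entrance_point is None:
            errors.append("school entrance unspecified")
        if sc.entrance_node is not None and sc.entrance_node not in self.nodes:
            errors.append(f"unknown entrance node {sc.entrance_node}")
        if sc.access_edge_ids:
            for e_id in sc.access_edge_ids:
                if e_id not in self.edges:
                    errors.append(f"unknown access edge {e_id}")
        for d in sc.driveway_nodes:
            if d not in self.nodes or self.nodes[d].kind != "driveway":
                errors.append(f"school driveway {d} is not a driveway node")
        if errors:
            raise NetworkError("; ".join(errors))

    def degree(self, node_id: str) -> int:
        return self._graph.degree(node_id) if node_id in self._graph else 0

    def incident_edges(self, node_id: str) -> list:
        if node_id not in self._graph:
            return []
        return sorted(k for _, _, k in self._graph.edges(node_id, keys=True))

    def entrance_xy(self) -> Tuple[float, float]:
        sc = self.school
        if sc.entrance_point is not None:
            return tuple(sc.entrance_point)
        node = self.nodes[sc.entrance_node]
        if node.kind == "driveway":
            return self.point_on_edge(node.host_edge, 0.5)
        return (node.x, node.y)

    def point_on_edge(self, edge_id: str, t: float) -> Tuple[float, float]:
        e = self.edges[edge_id]
        a, b = self.nodes[e.node_a], self.nodes[e.node_b]
        return (a.x + t * (b.x - a.x), a.y + t * (b.y - a.y))

    def distance_to_edge(self, point: Tuple[float, float], edge_id: str) -> float:
        return self.edge_projection(point, edge_id)[0]

    def edge_projection(
        self, point: Tuple[float, float], edge_id: str
    ) -> Tuple[float, float]:
        """(clamped distance, unclamped projection parameter t) for an edge.

        t in [0, 1] means the point lies alongside the edge (its
        perpendicular foot falls within the segment span).
        """
        px, py = point
        e = self.edges[edge_id]
        a, b = self.nodes[e.node_a], self.nodes[e.node_b]
        ax, ay, bx, by = a.x, a.y, b.x, b.y
        dx, dy = bx - ax, by - ay
        length_sq = dx * dx + dy * dy
        if length_sq == 0.0:
            return math.hypot(px - ax, py - ay), 0.0
        t_raw = ((px - ax) * dx + (py - ay) * dy) / length_sq
        t = max(0.0, min(1.0, t_raw))
        dist = math.hypot(px - (ax + t * dx), py - (ay + t * dy))
        return dist, t_raw


@dataclass(frozen=True)
class ObservationRoute:
    access_segments: tuple  # edge_ids
    crossings: tuple  # node_ids (intersections and school driveways)
    other_segments: tuple  # (edge_id, side) pairs


def identify_access_segments(network: StreetNetwork) -> list:
    """Edge(s) fronting the school entrance.

    Explicit ``access_edge_ids`` win (after adjacency validation); otherwise
    the nearest edge(s) to the entrance point are returned — ties (as when
    an intersection splits the frontage across two collinear edges) yield
    multiple access segments.  An entrance that cannot be tied to any edge
    is an error.
    """
    sc = network.school
    entrance = network.entrance_xy()

    if sc.access_edge_ids:
        edges = list(dict.fromkeys(sc.access_edge_ids))
        dmin = min(network.distance_to_edge(entrance, e) for e in edges)
        nearest_all = min(
            network.distance_to_edge(entrance, e) for e in network.edges
        )
        if dmin > nearest_all + _tie_tolerance(network):
            raise NetworkError(
                "declared access edges are not adjacent to the school entrance"
            )
        return sorted(edges)

    if sc.entrance_node is not None:
        node = network.nodes[sc.entrance_node]
        if node.kind == "driveway":
            return [node.host_edge]
        incident = network.incident_edges(sc.entrance_node)
        if not incident:
            raise NetworkError(
                f"entrance node {sc.entrance_node} is not adjacent to any edge"
            )
        return incident

    if not network.edges:
        raise NetworkError("network has no edges")
    proj = {e: network.edge_projection(entrance, e) for e in network.edges}
    dmin = min(d for d, _ in proj.values())
    tol = _tie_tolerance(network)
    nearest = [e for e, (d, _) in proj.items() if d <= dmin + tol]
    # Among equally near edges, true frontage is the edge(s) the entrance
    # lies alongside; a cross street meeting the frontage at the tying
    # endpoint only touches it end-on (projection outside the span).
    alongside = [e for e in nearest if -1e-9 <= proj[e][1] <= 1 + 1e-9]
    return sorted(alongside or nearest)


def _tie_tolerance(network: StreetNetwork) -> float:
    """Absolute distance slack for frontage ties, scaled to network extent."""
    xs = [n.x for n in network.nodes.values()]
    ys = [n.y for n in network.nodes.values()]
    extent = max(max(xs) - min(xs), max(ys) - min(ys), 1.0)
    return 1e-9 * extent


def entrance_side(network: StreetNetwork, edge_id: str) -> str:
    """Which side of the edge the school entrance lies on.

    Sides are labelled relative to the edge direction from the
    lexicographically smaller to the larger endpoint id: 'left' when the
    entrance is left of that direction (or collinear), else 'right'.
    """
    e = network.edges[edge_id]
    a_id, b_id = sorted((e.node_a, e.node_b))
    a, b = network.nodes[a_id], network.nodes[b_id]
    px, py = network.entrance_xy()
    cross = (b.x - a.x) * (py - a.y) - (b.y - a.y) * (px - a.x)
    return "left" if cross >= 0 else "right"


def select_route(network: StreetNetwork) -> ObservationRoute:
    """Nearest-neighbor observation route for one school.

    Crossings are the intersection endpoints of the access segments where
    streets actually meet (dead ends are not crossings) plus the school's
    own driveways on an access segment.  Other segments are every street
    incident to an intersection crossing except the access segments, each
    taken on the single audited side (the side facing the school).  Output
    lists are id-sorted, so the route is independent of insertion order.
    """
    access = identify_access_segments(network)
    access_set = set(access)

    intersection_crossings: set = set()
    for e_id in access:
        e = network.edges[e_id]
        for endpoint in (e.node_a, e.node_b):
            if network.degree(endpoint) >= 2:
                intersection_crossings.add(endpoint)

    driveway_crossings = {
        d for d in network.school.driveway_nodes
        if network.nodes[d].host_edge in access_set
    }

    other: set = set()
    for c in sorted(intersection_crossings):
        for e_id in network.incident_edges(c):
            if e_id not in access_set:
                other.add((e_id, entrance_side(network, e_id)))

    return ObservationRoute(
        access_segments=tuple(sorted(access_set)),
        crossings=tuple(sorted(intersection_crossings | driveway_crossings)),
        other_segments=tuple(sorted(other)),
    )


def count_route_units(route: ObservationRoute) -> tuple:
    """(n_access_segments, n_crossings, n_other_segments)."""
    return (
        len(route.access_segments),
        len(route.crossings),
        len(route.other_segments),
    )


# ---------------------------------------------------------------------------
# file I/O: nodes.csv / edges.csv / school.json


def read_network(directory: Union[str, Path]) -> StreetNetwork:
    directory = Path(directory)
    nodes_df = pd.read_csv(directory / "nodes.csv", dtype={"id": str, "host_edge": str})
    edges_df = pd.read_csv(
        directory / "edges.csv", dtype={"id": str, "node_a": str, "node_b": str}
    )
    school_raw = json.loads((directory / "school.json").read_text())
    nodes = {}
    for row in nodes_df.itertuples(index=False):
        host = getattr(row, "host_edge", None)
        if isinstance(host, float) and math.isnan(host):
            host = None
        nodes[str(row.id)] = Node(str(row.id), float(row.x), float(row.y),
                                  str(row.kind), host)
    edges = {
        str(r.id): Edge(str(r.id), str(r.node_a), str(r.node_b),
                        str(getattr(r, "street_name", "")))
        for r in edges_df.itertuples(index=False)
    }
    school = School(
        entrance_node=school_raw.get("entrance_node"),
        entrance_point=(
            tuple(school_raw["entrance_point"])
            if school_raw.get("entrance_point") else None
        ),
        access_edge_ids=(
            tuple(school_raw["access_edge_ids"])
            if school_raw.get("access_edge_ids") else None
        ),
        driveway_nodes=tuple(school_raw.get("driveway_nodes", ())),
    )
    return StreetNetwork(nodes, edges, school)


def write_network(network: StreetNetwork, directory: Union[str, Path]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"id": n.node_id, "x": n.x, "y": n.y, "kind": n.kind,
             "host_edge": n.host_edge or ""}
            for n in sorted(network.nodes.values(), key=lambda n: n.node_id)
        ]
    ).to_csv(directory / "nodes.csv", index=False)
    pd.DataFrame(
        [
            {"id": e.edge_id, "node_a": e.node_a, "node_b": e.node_b,
             "street_name": e.street_name}
            for e in sorted(network.edges.values(), key=lambda e: e.edge_id)
        ]
    ).to_csv(directory / "edges.csv", index=False)
    sc = network.school
    (directory / "school.json").write_text(
        json.dumps(
            {
                "entrance_node": sc.entrance_node,
                "entrance_point": list(sc.entrance_point) if sc.entrance_point else None,
                "access_edge_ids": list(sc.access_edge_ids) if sc.access_edge_ids else None,
                "driveway_nodes": list(sc.driveway_nodes),
            },
            indent=1,
        )
    )


def route_to_dict(route: ObservationRoute) -> dict:
    n_access, n_crossings, n_other = count_route_units(route)
    return {
        "access_segments": list(route.access_segments),
        "crossings": list(route.crossings),
        "other_segments": [list(pair) for pair in route.other_segments],
        "counts": {
            "access_segments": n_access,
            "crossings": n_crossings,
            "other_segments": n_other,
        },
    }
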