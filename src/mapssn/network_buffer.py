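"""Street networks, network service-area buffers and the audit sampling frame.

The audit catchment of a school is the set of network locations within a
threshold shortest-path distance (default 500 m) of the school's address
point, walked along the road centrelines ("service area" / street-network
buffer).  From that buffer the module extracts the sampling frame:

* street segments — maximal inter-junction road pieces intersecting the
  buffer, each duplicated into odd/even sides by address parity;
* intersections — junctions with >= 3 connecting roads (degree-2 nodes are
  artefacts of line splitting, never audited);

and applies the boundary protocol: boundary segments without a residence
are excluded, and segments covered from both ends with residences at each
end and majority coverage are extended to full segments.

All coordinates are planar metric (projected); distances are metres.
One-way restrictions are ignored: buffers model pedestrians, not cars.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, shape

from .audit_model import Intersection, StreetSegment
from .errors import GeocodingError, MapsSNError

_COORD_NDIGITS = 6  # junction matching tolerance (~1 um in projected metres)


def _key(xy: Sequence[float]) -> tuple[float, float]:
    return (round(float(xy[0]), _COORD_NDIGITS), round(float(xy[1]), _COORD_NDIGITS))


@dataclass(frozen=True)
class Edge:
    """One inter-junction road piece of the split network."""

    edge_id: str
    u: str
    v: str
    coords: tuple[tuple[float, float], ...]
    length_m: float

    @cached_property
    def line(self) -> LineString:
        return LineString(self.coords)


@dataclass(frozen=True)
class AddressPoint:
    point: tuple[float, float]
    number: int
    edge_id: str
    offset_m: float  # position along the edge, measured from endpoint u

    @property
    def parity(self) -> str:
        return "odd" if self.number % 2 else "even"


class StreetNetwork:
    """Junctions, split road edges, address points and land-use parcels.

    Input road centrelines are split at junctions: every coordinate that is
    an endpoint of some input line becomes a node, and any line passing
    through such a coordinate as an interior vertex is cut there.  A single
    road crossing three junctions therefore yields two edges.
    """

    def __init__(self, edges: Iterable[Edge],
                 addresses: Iterable[AddressPoint] = (),
                 land_use_parcels: Iterable[tuple[Polygon, str]] = ()):
        self.edges: dict[str, Edge] = {e.edge_id: e for e in edges}
        self.nodes: dict[str, tuple[float, float]] = {}
        for e in self.edges.values():
            self.nodes.setdefault(e.u, _key(e.coords[0]))
            self.nodes.setdefault(e.v, _key(e.coords[-1]))
        self.address_points: list[AddressPoint] = list(addresses)
        self.land_use_parcels: list[tuple[Polygon, str]] = list(land_use_parcels)
        self._graph: nx.MultiGraph | None = None
        self._addr_by_edge: dict[str, list[AddressPoint]] | None = None

    # -- construction -----------------------------------------------------
    @classmethod
    def from_lines(cls, lines: Sequence[tuple[str, Sequence[Sequence[float]]]],
                   addresses: Sequence[tuple[Sequence[float], int]] = (),
                   land_use: Sequence[tuple[Polygon, str]] = ()) -> "StreetNetwork":
        """Build a network from (street_id, coordinate list) pairs.

        Lines are split at junction coordinates; addresses are snapped to
        their nearest edge.
        """
        # a coordinate is a junction if it ends a line or is shared by >= 2 lines
        seen_in: dict[tuple[float, float], set[int]] = {}
        endpoints: set[tuple[float, float]] = set()
        for li, (_, coords) in enumerate(lines):
            endpoints.update((_key(coords[0]), _key(coords[-1])))
            for xy in coords:
                seen_in.setdefault(_key(xy), set()).add(li)
        junctions: dict[tuple[float, float], str] = {}
        for _, coords in lines:
            for xy in coords:
                k = _key(xy)
                if (k in endpoints or len(seen_in[k]) >= 2) and k not in junctions:
                    junctions[k] = f"N{len(junctions)}"

        edges: list[Edge] = []
        for street_id, coords in lines:
            pieces: list[list[Sequence[float]]] = [[coords[0]]]
            for xy in coords[1:-1]:
                pieces[-1].append(xy)
                if _key(xy) in junctions:  # interior junction: cut here
                    pieces.append([xy])
            pieces[-1].append(coords[-1])
            for part, piece in enumerate(pieces, start=1):
                coords = tuple(_key(p) for p in piece)
                line = LineString(coords)
                if line.length == 0:
                    raise MapsSNError(f"street {street_id}: zero-length piece")
                eid = f"{street_id}.{part:02d}" if len(pieces) > 1 else str(street_id)
                edges.append(Edge(edge_id=eid,
                                  u=junctions[coords[0]],
                                  v=junctions[coords[-1]],
                                  coords=coords,
                                  length_m=line.length))
        net = cls(edges)
        net.add_addresses(addresses)
        net.land_use_parcels = list(land_use)
        return net

    @classmethod
    def from_geojson(cls, edges: str | Path | Mapping,
                     addresses: str | Path | Mapping | None = None,
                     land_use: str | Path | Mapping | None = None) -> "StreetNetwork":
        """Build a network from GeoJSON FeatureCollections.

        Edges are LineStrings (property ``street`` or ``id`` names the
        street), addresses are Points with a ``number`` property, land-use
        parcels are Polygons with a ``category`` property.
        """
        edge_fc = _load_fc(edges)
        lines = []
        for i, feat in enumerate(edge_fc["features"]):
            geom = feat["geometry"]
            if geom["type"] != "LineString":
                raise MapsSNError(f"edge feature {i}: expected LineString")
            props = feat.get("properties") or {}
            street = props.get("street") or props.get("id") or f"S{i:03d}"
            lines.append((str(street), geom["coordinates"]))
        addr = []
        if addresses is not None:
            for feat in _load_fc(addresses)["features"]:
                addr.append((feat["geometry"]["coordinates"],
                             int(feat["properties"]["number"])))
        parcels = []
        if land_use is not None:
            for feat in _load_fc(land_use)["features"]:
                parcels.append((shape(feat["geometry"]),
                                feat["properties"]["category"]))
        return cls.from_lines(lines, addr, parcels)

    def to_geojson(self) -> dict:
        feats = [{"type": "Feature",
                  "properties": {"id": e.edge_id, "length_m": e.length_m},
                  "geometry": {"type": "LineString",
                               "coordinates": [list(c) for c in e.coords]}}
                 for e in self.edges.values()]
        return {"type": "FeatureCollection", "features": feats}

    def add_address(self, point: tuple[float, float], number: int) -> AddressPoint:
        """Attach an address point to its nearest edge."""
        return self.add_addresses([(point, number)])[0]

    def add_addresses(self, pairs: Sequence[tuple[Sequence[float], int]]
                      ) -> list[AddressPoint]:
        """Bulk-attach address points to their nearest edges (STRtree)."""
        if not pairs:
            return []
        from shapely.strtree import STRtree
        edge_list = list(self.edges.values())
        tree = STRtree([e.line for e in edge_list])
        pts = [Point(xy) for xy, _ in pairs]
        idx = tree.query_nearest(pts)
        nearest = dict(zip(idx[0], idx[1]))
        out = []
        for i, (xy, number) in enumerate(pairs):
            e = edge_list[nearest[i]]
            ap = AddressPoint(point=(float(xy[0]), float(xy[1])),
                              number=int(number), edge_id=e.edge_id,
                              offset_m=float(e.line.project(pts[i])))
            self.address_points.append(ap)
            out.append(ap)
        return out

    # -- graph view -------------------------------------------------------
    @property
    def graph(self) -> nx.MultiGraph:
        if self._graph is None:
            g = nx.MultiGraph()
            g.add_nodes_from(self.nodes)
            for e in self.edges.values():
                g.add_edge(e.u, e.v, key=e.edge_id, length=e.length_m)
            self._graph = g
        return self._graph

    def node_degree(self, node_id: str) -> int:
        return self.graph.degree(node_id)

    def addresses_on(self, edge_id: str) -> list[AddressPoint]:
        if self._addr_by_edge is None or sum(
                map(len, self._addr_by_edge.values())) != len(self.address_points):
            by_edge: dict[str, list[AddressPoint]] = {}
            for a in self.address_points:
                by_edge.setdefault(a.edge_id, []).append(a)
            self._addr_by_edge = by_edge
        return self._addr_by_edge.get(edge_id, [])


def _load_fc(source: str | Path | Mapping) -> Mapping:
    if isinstance(source, Mapping):
        return source
    with open(source) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# service area

Interval = tuple[float, float]


@dataclass
class BufferZone:
    """Network service area: covered intervals along each edge whose
    shortest-path distance from the origin is within the threshold."""

    school_id: str
    origin_edge: str
    origin_offset_m: float
    threshold_m: float
    covered_edges: dict[str, list[Interval]] = field(default_factory=dict)
    node_dist: dict[str, float] = field(default_factory=dict)

    def covered_length(self, edge_id: str | None = None) -> float:
        if edge_id is not None:
            return sum(b - a for a, b in self.covered_edges.get(edge_id, []))
        return sum(self.covered_length(e) for e in self.covered_edges)

    def contains(self, other: "BufferZone", tol: float = 1e-9) -> bool:
        """True if every covered interval of ``other`` lies inside this zone."""
        for eid, intervals in other.covered_edges.items():
            mine = self.covered_edges.get(eid, [])
            for a, b in intervals:
                if not any(ma - tol <= a and b <= mb + tol for ma, mb in mine):
                    return False
        return True

    def to_geojson(self, network: StreetNetwork) -> dict:
        feats = []
        for eid, intervals in self.covered_edges.items():
            line = network.edges[eid].line
            for a, b in intervals:
                sub = _substring(line, a, b)
                feats.append({"type": "Feature",
                              "properties": {"edge_id": eid, "from_m": a, "to_m": b},
                              "geometry": json.loads(json.dumps(sub.__geo_interface__))})
        return {"type": "FeatureCollection", "features": feats}


def _substring(line: LineString, a: float, b: float) -> LineString:
    from shapely.ops import substring
    return substring(line, a, b)


def _merge(intervals: list[Interval], tol: float = 1e-9) -> list[Interval]:
    out: list[Interval] = []
    for a, b in sorted(intervals):
        if b - a <= tol:
            continue
        if out and a <= out[-1][1] + tol:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def snap_to_network(network: StreetNetwork, point: Sequence[float],
                    snap_radius_m: float = 50.0) -> tuple[str, float]:
    """Snap a point to (edge_id, offset along edge); error beyond the radius."""
    if not network.edges:
        raise GeocodingError("empty network")
    p = Point(point)
    best = min(network.edges.values(), key=lambda e: e.line.distance(p))
    d = best.line.distance(p)
    if d > snap_radius_m:
        raise GeocodingError(
            f"point {tuple(point)} is {d:.1f} m from the nearest road"
            f" (snap radius {snap_radius_m} m)")
    return best.edge_id, float(best.line.project(p))


def compute_service_area(network: StreetNetwork, school: Sequence[float],
                         threshold_m: float = 500.0,
                         school_id: str = "S01",
                         snap_radius_m: float = 50.0) -> BufferZone:
    """Compute the street-network buffer around a school address point.

    The school is snapped to the nearest edge; shortest-path distances are
    taken along the network (undirected), and each edge carries the covered
    interval(s) of points within ``threshold_m``.  A disconnected origin
    component simply yields a zone restricted to that component.
    """
    if threshold_m < 0:
        raise MapsSNError("threshold_m must be >= 0")
    eid, t0 = snap_to_network(network, school, snap_radius_m)
    e0 = network.edges[eid]

    g = nx.Graph()  # parallel edges collapsed to their minimum length
    for e in network.edges.values():
        if g.has_edge(e.u, e.v):
            g[e.u][e.v]["length"] = min(g[e.u][e.v]["length"], e.length_m)
        else:
            g.add_edge(e.u, e.v, length=e.length_m)
    g.add_node("__origin__")
    t0 = min(max(t0, 0.0), e0.length_m)
    g.add_edge("__origin__", e0.u, length=t0)
    g.add_edge("__origin__", e0.v, length=max(e0.length_m - t0, 0.0))
    dist = nx.single_source_dijkstra_path_length(g, "__origin__", weight="length")

    covered: dict[str, list[Interval]] = {}
    for e in network.edges.values():
        intervals: list[Interval] = []
        du = dist.get(e.u, math.inf)
        dv = dist.get(e.v, math.inf)
        if du <= threshold_m:
            intervals.append((0.0, min(e.length_m, threshold_m - du)))
        if dv <= threshold_m:
            intervals.append((max(0.0, e.length_m - (threshold_m - dv)), e.length_m))
        if e.edge_id == eid:  # direct reach from the on-edge origin
            intervals.append((max(0.0, t0 - threshold_m),
                              min(e.length_m, t0 + threshold_m)))
        merged = _merge(intervals)
        if merged:
            covered[e.edge_id] = merged
    node_dist = {n: dist[n] for n in network.nodes if n in dist}
    return BufferZone(school_id=school_id, origin_edge=eid, origin_offset_m=t0,
                      threshold_m=threshold_m, covered_edges=covered,
                      node_dist=node_dist)


# ---------------------------------------------------------------------------
# sampling frame extraction

def extract_segments(network: StreetNetwork, buffer: BufferZone) -> list[StreetSegment]:
    """One street segment per inter-junction edge intersecting the buffer.

    Residence counts per side come from address-number parity over the
    addresses snapped to the edge.  Coverage is half-open: an edge touching
    the buffer frontier at a single point is not included.
    """
    segments = []
    for eid in sorted(buffer.covered_edges):
        e = network.edges[eid]
        cov = buffer.covered_length(eid)
        if cov <= 0:
            continue
        addrs = network.addresses_on(eid)
        segments.append(StreetSegment(
            segment_id=f"{buffer.school_id}.{eid}",
            school_id=buffer.school_id,
            length_m=e.length_m,
            endpoint_nodes=(e.u, e.v),
            residences_odd=sum(1 for a in addrs if a.parity == "odd"),
            residences_even=sum(1 for a in addrs if a.parity == "even"),
            coverage_fraction=min(1.0, cov / e.length_m)))
    return segments


@dataclass(frozen=True)
class CoverageDetail:
    """End-coverage structure of a partially covered segment: intervals
    along the edge, residences inside each interval, and the uncovered gap."""

    intervals: tuple[Interval, ...]
    residences_per_interval: tuple[int, ...]
    gap_m: float
    covers_both_ends: bool


def coverage_details(network: StreetNetwork, buffer: BufferZone) -> dict[str, CoverageDetail]:
    """Per-segment coverage structure, keyed by segment id."""
    out = {}
    for eid, intervals in buffer.covered_edges.items():
        e = network.edges[eid]
        addrs = network.addresses_on(eid)
        res = tuple(sum(1 for a in addrs if lo - 1e-9 <= a.offset_m <= hi + 1e-9)
                    for lo, hi in intervals)
        cov = sum(hi - lo for lo, hi in intervals)
        both = (len(intervals) >= 2
                and intervals[0][0] <= 1e-9
                and intervals[-1][1] >= e.length_m - 1e-9)
        out[f"{buffer.school_id}.{eid}"] = CoverageDetail(
            intervals=tuple(intervals), residences_per_interval=res,
            gap_m=e.length_m - cov, covers_both_ends=both)
    return out


def identify_intersections(network: StreetNetwork, buffer: BufferZone) -> list[Intersection]:
    """Buffer-interior junctions with >= 3 connecting roads, each listing all
    connecting roads (one crossing audit per connecting road)."""
    out = []
    for node in sorted(network.nodes):
        d = buffer.node_dist.get(node, math.inf)
        if d > buffer.threshold_m:
            continue
        roads = tuple(sorted(
            eid for eid, e in network.edges.items() if node in (e.u, e.v)))
        if len(roads) >= 3:
            out.append(Intersection(node_id=node, connecting_roads=roads,
                                    school_id=buffer.school_id))
    return out


def apply_protocol_rules(
        segments: Iterable[StreetSegment],
        details: Mapping[str, CoverageDetail] | None = None,
) -> tuple[list[StreetSegment], pd.DataFrame, pd.DataFrame]:
    """Boundary inclusion/extension rules for partially covered segments.

    * Exclusion: a boundary segment (coverage < 1) with no residence on
      either side is dropped and logged with its length.
    * Extension: a segment covered from both ends, with at least one
      residence in each covered end and strictly more than half its length
      covered, is extended to a full segment; the bridged gap is logged.
      (End structure comes from ``details``; without it no segment extends.)

    Returns (kept segments, exclusion log, extension log).
    """
    kept: list[StreetSegment] = []
    excl_rows, ext_rows = [], []
    for seg in segments:
        if seg.coverage_fraction < 1.0 and seg.residences_total == 0:
            excl_rows.append({"segment_id": seg.segment_id,
                              "length_m": seg.length_m,
                              "coverage_fraction": seg.coverage_fraction})
            continue
        det = (details or {}).get(seg.segment_id)
        if (seg.coverage_fraction < 1.0 and det is not None
                and det.covers_both_ends
                and det.residences_per_interval[0] >= 1
                and det.residences_per_interval[-1] >= 1
                and seg.coverage_fraction > 0.5):
            ext_rows.append({"segment_id": seg.segment_id,
                             "length_m": seg.length_m,
                             "gap_m": det.gap_m,
                             "coverage_fraction": seg.coverage_fraction})
            seg = StreetSegment(
                segment_id=seg.segment_id, school_id=seg.school_id,
                length_m=seg.length_m, endpoint_nodes=seg.endpoint_nodes,
                residences_odd=seg.residences_odd,
                residences_even=seg.residences_even,
                coverage_fraction=1.0)
        kept.append(seg)
    excl = pd.DataFrame(excl_rows, columns=["segment_id", "length_m",
                                            "coverage_fraction"])
    ext = pd.DataFrame(ext_rows, columns=["segment_id", "length_m", "gap_m",
                                          "coverage_fraction"])
    return kept, excl, ext


def subdivide_segment(length_m: float) -> list[float]:
    """Equal subdivision keeping audited pieces at most 200 m.

    <= 200 m stays whole; 200-400 m splits in half; 400-600 m in thirds;
    longer segments split into ceil(length/200) equal pieces.
    """
    if length_m <= 0:
        raise MapsSNError("length_m must be > 0")
    if length_m <= 200:
        return [length_m]
    if length_m <= 400:
        n = 2
    elif length_m <= 600:
        n = 3
    else:
        n = math.ceil(length_m / 200)
    return [length_m / n] * n


# ---------------------------------------------------------------------------
# worksheets

def segments_worksheet(segments: Iterable[StreetSegment]) -> pd.DataFrame:
    """Sampling-frame worksheet: one row per street side."""
    rows = []
    for seg in segments:
        for side in seg.sides():
            rows.append({"side_id": side.side_id, "segment_id": seg.segment_id,
                         "school_id": seg.school_id, "parity": side.parity,
                         "length_m": seg.length_m,
                         "coverage_fraction": seg.coverage_fraction,
                         "residences": (seg.residences_odd if side.parity == "odd"
                                        else seg.residences_even)})
    return pd.DataFrame(rows)


def intersections_worksheet(intersections: Iterable[Intersection]) -> pd.DataFrame:
    rows = [{"node_id": x.node_id, "school_id": x.school_id,
             "degree": x.degree,
             "connecting_roads": ";".join(x.connecting_roads)}
            for x in intersections]
    return pd.DataFrame(rows)
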