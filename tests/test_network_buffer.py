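"""Service-area construction, sampling-frame extraction, protocol rules."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mapssn.audit_model import StreetSegment
from mapssn.errors import GeocodingError, MapsSNError
from mapssn.network_buffer import (CoverageDetail, StreetNetwork,
                                   apply_protocol_rules, compute_service_area,
                                   coverage_details, extract_segments,
                                   identify_intersections, subdivide_segment)


def brute_force_covered(network, origin_node, threshold, step=1.0):
    """Independent oracle: Floyd-Warshall node distances plus dense sampling
    of points along every edge."""
    nodes = sorted(network.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for e in network.edges.values():
        i, j = idx[e.u], idx[e.v]
        d[i, j] = min(d[i, j], e.length_m)
        d[j, i] = d[i, j]
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    o = idx[origin_node]
    out = {}
    for eid, e in network.edges.items():
        ts = np.arange(0.0, e.length_m + step / 2, step)
        dist = np.minimum(d[o, idx[e.u]] + ts,
                          d[o, idx[e.v]] + (e.length_m - ts))
        out[eid] = (ts, dist)
    return out


class TestServiceArea:
    def test_path_coverage_arithmetic(self, path_network):
        # origin O, threshold 500: O-A (300 m) full, A-B covered for 200 m
        buf = compute_service_area(path_network, (0.0, 0.0), 500.0)
        assert buf.covered_length("main.01") == pytest.approx(300.0)
        assert buf.covered_length("main.02") == pytest.approx(200.0)

    def test_zero_threshold_covers_nothing_but_origin(self, path_network):
        buf = compute_service_area(path_network, (0.0, 0.0), 0.0)
        assert buf.covered_length() == 0.0

    def test_geocoding_error_beyond_snap_radius(self, path_network):
        with pytest.raises(GeocodingError):
            compute_service_area(path_network, (0.0, 500.0), 500.0,
                                 snap_radius_m=50.0)

    def test_disconnected_component_is_silently_restricted(self):
        net = StreetNetwork.from_lines([
            ("a", [(0.0, 0.0), (100.0, 0.0)]),
            ("b", [(0.0, 1000.0), (100.0, 1000.0)]),
        ])
        buf = compute_service_area(net, (0.0, 0.0), 400.0)
        assert "a" in buf.covered_edges and "b" not in buf.covered_edges

    @pytest.mark.parametrize("threshold", [150.0, 300.0, 500.0])
    def test_intervals_match_brute_force_oracle(self, grid_network, threshold):
        buf = compute_service_area(grid_network, (0.0, 0.0), threshold)
        oracle = brute_force_covered(grid_network, "N0", threshold)
        for eid in grid_network.edges:
            intervals = buf.covered_edges.get(eid, [])
            ts, dist = oracle[eid]
            for t, d in zip(ts, dist):
                if abs(d - threshold) <= 1e-9:
                    continue  # frontier point: zero covered measure, either way
                inside = any(a - 1e-9 <= t <= b + 1e-9 for a, b in intervals)
                assert inside == (d < threshold), (eid, t, d)

    def test_monotone_in_threshold(self, grid_network):
        # centre-origin 300 m zone strictly inside the 500 m zone
        centre = (100.0, 100.0)
        small = compute_service_area(grid_network, centre, 300.0)
        large = compute_service_area(grid_network, centre, 500.0)
        assert large.contains(small)
        assert not small.contains(large)
        assert small.covered_length() < large.covered_length()


class TestSegments:
    def test_polyline_through_junction_splits_in_two(self, path_network):
        # one road crossing 3 junctions -> 2 segments
        buf = compute_service_area(path_network, (0.0, 0.0), 1000.0)
        segs = extract_segments(path_network, buf)
        main = [s for s in segs if ".main" in s.segment_id]
        assert len(main) == 2

    def test_house_number_parity_assignment(self, path_network):
        for num in (2, 4, 6):
            path_network.add_address((float(10 * num), 5.0), num)
        for num in (1, 3):
            path_network.add_address((float(10 * num), -5.0), num)
        buf = compute_service_area(path_network, (0.0, 0.0), 250.0)
        seg = [s for s in extract_segments(path_network, buf)
               if s.segment_id.endswith("main.01")][0]
        assert seg.residences_even == 3
        assert seg.residences_odd == 2

    def test_partition_of_covered_length(self, grid_network):
        buf = compute_service_area(grid_network, (100.0, 100.0), 350.0)
        segs = extract_segments(grid_network, buf)
        total = sum(s.coverage_fraction * s.length_m for s in segs)
        assert total == pytest.approx(buf.covered_length(), rel=1e-9)

    def test_every_segment_has_two_sides_and_unique_id(self, grid_network):
        buf = compute_service_area(grid_network, (100.0, 100.0), 500.0)
        segs = extract_segments(grid_network, buf)
        ids = [s.segment_id for s in segs]
        assert len(ids) == len(set(ids))
        for s in segs:
            odd, even = s.sides()
            assert {odd.parity, even.parity} == {"odd", "even"}


class TestIntersections:
    def test_degree_two_nodes_are_false_intersections(self, path_network):
        buf = compute_service_area(path_network, (0.0, 0.0), 1000.0)
        inter = identify_intersections(path_network, buf)
        # A has degree 3 (two main pieces + stub); O and B have degree 1
        assert [x.degree for x in inter] == [3]
        assert len(inter[0].connecting_roads) == 3

    def test_shares_partition(self, grid_network):
        buf = compute_service_area(grid_network, (100.0, 100.0), 600.0)
        inter = identify_intersections(grid_network, buf)
        by_deg = {}
        for x in inter:
            by_deg[x.degree] = by_deg.get(x.degree, 0) + 1
        assert sum(by_deg.values()) == len(inter)
        assert set(by_deg) == {3, 4}  # 4x4 grid: edge nodes 3-way, interior 4-way
        assert by_deg[3] == 8 and by_deg[4] == 4

    def test_outside_buffer_excluded(self, grid_network):
        buf = compute_service_area(grid_network, (0.0, 0.0), 150.0)
        inter = identify_intersections(grid_network, buf)
        assert {x.node_id for x in inter} <= {
            n for n, d in buf.node_dist.items() if d <= 150.0}


def _seg(seg_id="S01.E1", length=100.0, cov=1.0, odd=0, even=0):
    return StreetSegment(segment_id=seg_id, school_id="S01", length_m=length,
                         endpoint_nodes=("a", "b"), residences_odd=odd,
                         residences_even=even, coverage_fraction=cov)


class TestProtocolRules:
    def test_boundary_segment_without_residence_excluded(self):
        kept, excl, ext = apply_protocol_rules([_seg(length=15.0, cov=0.4)])
        assert kept == [] and len(excl) == 1
        assert excl.iloc[0].length_m == 15.0

    def test_fully_covered_segment_without_residence_kept(self):
        kept, excl, _ = apply_protocol_rules([_seg(cov=1.0)])
        assert len(kept) == 1 and excl.empty

    def test_boundary_segment_with_residence_kept(self):
        kept, excl, _ = apply_protocol_rules([_seg(cov=0.3, odd=1)])
        assert len(kept) == 1 and excl.empty

    def _both_end_detail(self, gap=50.0, res=(1, 1)):
        return {"S01.E1": CoverageDetail(
            intervals=((0.0, 100.0), (150.0, 250.0)),
            residences_per_interval=res, gap_m=gap, covers_both_ends=True)}

    def test_majority_coverage_with_residences_extends(self):
        seg = _seg(length=250.0, cov=0.8, odd=1, even=1)
        kept, _, ext = apply_protocol_rules([seg], self._both_end_detail())
        assert kept[0].coverage_fraction == 1.0
        assert len(ext) == 1 and ext.iloc[0].gap_m == 50.0

    def test_no_extension_at_half_coverage_or_less(self):
        seg = _seg(length=250.0, cov=0.5, odd=1, even=1)
        kept, _, ext = apply_protocol_rules([seg], self._both_end_detail())
        assert ext.empty and kept[0].coverage_fraction == 0.5

    def test_no_extension_without_residence_at_each_end(self):
        seg = _seg(length=250.0, cov=0.8, odd=1)
        kept, _, ext = apply_protocol_rules(
            [seg], self._both_end_detail(res=(1, 0)))
        assert ext.empty

    def test_exclusion_never_removes_inhabited_segment(self):
        segs = [_seg(seg_id=f"S01.E{i}", cov=0.2, odd=i % 2, even=0)
                for i in range(10)]
        kept, excl, _ = apply_protocol_rules(segs)
        assert all(s.residences_total > 0 for s in kept)
        assert all(r == 0 for r in
                   (s.residences_total for s in segs if s.segment_id
                    in set(excl.segment_id)))

    def test_pipeline_detects_and_extends_two_ended_coverage(self):
        # a curvy 500 m street runs parallel to a straight 300 m one; the
        # buffer reaches it from both ends leaving a 40 m central gap, with
        # a residence inside each covered end -> the segment is extended
        net = StreetNetwork.from_lines([
            ("short", [(0.0, 0.0), (300.0, 0.0)]),
            ("long", [(0.0, 0.0), (150.0, 200.0), (300.0, 0.0)]),
        ])
        net.add_address((60.0, 80.0), 1)   # offset 100 on the long street
        net.add_address((282.0, 24.0), 2)  # offset 470 on the long street
        buf = compute_service_area(net, (0.0, 0.0), 380.0)
        assert buf.covered_edges["long"] == [
            pytest.approx((0.0, 380.0)), pytest.approx((420.0, 500.0))]
        segs = extract_segments(net, buf)
        details = coverage_details(net, buf)
        long_seg = next(s for s in segs if s.segment_id.endswith(".long"))
        assert long_seg.coverage_fraction == pytest.approx(0.92)
        kept, excl, ext = apply_protocol_rules(segs, details)
        assert len(ext) == 1
        assert ext.iloc[0].gap_m == pytest.approx(40.0)
        extended = next(s for s in kept if s.segment_id.endswith(".long"))
        assert extended.coverage_fraction == 1.0


class TestSubdivision:
    @pytest.mark.parametrize("length,expected", [
        (150.0, [150.0]),
        (200.0, [200.0]),
        (350.0, [175.0, 175.0]),
        (400.0, [200.0, 200.0]),
        (500.0, [500.0 / 3] * 3),
        (600.0, [200.0] * 3),
    ])
    def test_published_subdivision_rules(self, length, expected):
        assert subdivide_segment(length) == pytest.approx(expected)

    def test_non_positive_length_rejected(self):
        with pytest.raises(MapsSNError):
            subdivide_segment(0.0)

    @given(st.floats(min_value=0.1, max_value=5000.0))
    def test_pieces_sum_to_length(self, length):
        pieces = subdivide_segment(length)
        assert math.isclose(sum(pieces), length, rel_tol=1e-12)
        if length <= 600.0:
            assert all(p <= 200.0 + 1e-9 for p in pieces)
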