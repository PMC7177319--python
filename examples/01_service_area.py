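"""Street-network buffer around a school on a toy network.

Builds a small road network, computes the 500 m network service area from
the school address point, and prints the covered interval on each street
segment together with the boundary-protocol decisions.
"""
from mapssn.network_buffer import (StreetNetwork, apply_protocol_rules,
                                   compute_service_area, coverage_details,
                                   extract_segments, identify_intersections,
                                   subdivide_segment)

net = StreetNetwork.from_lines([
    ("main", [(0.0, 0.0), (300.0, 0.0), (700.0, 0.0), (900.0, 0.0)]),
    ("cross", [(300.0, -200.0), (300.0, 0.0), (300.0, 200.0)]),
])
net.add_address((150.0, 5.0), 1)   # odd side of the first main block
net.add_address((250.0, -5.0), 2)  # even side of the same block
# the second main block (300-700 m) is partially covered and uninhabited:
# the boundary protocol will exclude it from the audit

buf = compute_service_area(net, (0.0, 0.0), 500.0, school_id="S01")
print("covered length:", round(buf.covered_length(), 1), "m")
for eid, intervals in sorted(buf.covered_edges.items()):
    print(f"  {eid}: {[(round(a, 1), round(b, 1)) for a, b in intervals]}")

segs = extract_segments(net, buf)
kept, excluded, extended = apply_protocol_rules(segs, coverage_details(net, buf))
print(f"{len(segs)} segments, {len(kept)} kept after the residence rule,"
      f" {len(excluded)} excluded (uninhabited boundary pieces)")

inters = identify_intersections(net, buf)
print("intersections (>=3 connecting roads):",
      [(x.node_id, x.degree) for x in inters])

# long segments are subdivided for comparable audit units (<= 200 m pieces)
print("a 500 m segment audits as pieces of:",
      [round(p, 1) for p in subdivide_segment(500.0)], "m")
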