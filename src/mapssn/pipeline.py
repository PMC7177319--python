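"""End-to-end study assembly: city -> buffers -> frames -> audits -> scores.

Glue used by the command-line interface, the examples and the acceptance
script.  Everything here simply sequences the public module functions; no
scientific logic of its own beyond the documented choice of reliability
targets (street sides for route/segment measures, intersections for the
crossing measure).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .audit_model import AuditRecord, Intersection, ScoringScheme, StreetSegment
from .macro_metrics import MacroProfile, macro_profile, walkability
from .network_buffer import (BufferZone, StreetNetwork, apply_protocol_rules,
                             compute_service_area, coverage_details,
                             extract_segments, identify_intersections)
from .scoring import (aggregate_school, concordance_inputs, score_table,
                      unit_section_score)
from .reliability_stats import concordance
from .synthetic_data import CityConfig, generate_audits, generate_city, school_ids


@dataclass
class SchoolFrame:
    """Sampling frame and audits for one school neighbourhood."""

    school_id: str
    buffer: BufferZone
    segments: list[StreetSegment]
    intersections: list[Intersection]
    exclusions: pd.DataFrame
    extensions: pd.DataFrame
    records: list[AuditRecord] = field(default_factory=list)


@dataclass
class StudyResult:
    network: StreetNetwork
    schools: dict[str, tuple[float, float]]
    frames: dict[str, SchoolFrame]
    summaries: list  # SchoolSummary, all three side scopes per school
    paired: pd.DataFrame
    concordance: pd.DataFrame
    profiles: list[MacroProfile]
    walkability: pd.Series
    scores: pd.DataFrame


def build_frame(network: StreetNetwork, school_point: Sequence[float],
                school_id: str, threshold_m: float = 500.0) -> SchoolFrame:
    """Buffer, protocol-filtered segments and intersections for one school."""
    buf = compute_service_area(network, school_point, threshold_m,
                               school_id=school_id)
    segs = extract_segments(network, buf)
    details = coverage_details(network, buf)
    kept, excl, ext = apply_protocol_rules(segs, details)
    inters = identify_intersections(network, buf)
    return SchoolFrame(school_id=school_id, buffer=buf, segments=kept,
                       intersections=inters, exclusions=excl, extensions=ext)


def simulate_study(config: CityConfig, scheme: ScoringScheme,
                   threshold_m: float = 500.0,
                   corridor_radius_m: float = 95.0,
                   n_raters: int = 1) -> StudyResult:
    """Generate a synthetic city and run the full assessment pipeline."""
    network, schools = generate_city(config)
    frames: dict[str, SchoolFrame] = {}
    summaries = []
    profiles = []
    for idx, school in enumerate(school_ids(config)):
        frame = build_frame(network, schools[school], school, threshold_m)
        frame.records = generate_audits(frame.segments, frame.intersections,
                                        scheme, config, school_index=idx,
                                        n_raters=n_raters)
        frames[school] = frame
        rater1 = [r for r in frame.records if r.auditor_id == "A1"]
        for scope in ("odd", "even", "combined"):
            summaries.append(aggregate_school(rater1, scheme, scope,
                                              school_id=school))
        profiles.append(macro_profile(network, frame.buffer,
                                      n_junctions=len(frame.intersections),
                                      corridor_radius_m=corridor_radius_m))
    paired = concordance_inputs(summaries)
    # the odd/even correlation needs >= 3 complete school pairs
    conc = concordance(paired) if len(paired) >= 3 else pd.DataFrame()
    walk = walkability(profiles) if len(profiles) >= 2 else pd.Series(dtype=float)
    return StudyResult(network=network, schools=schools, frames=frames,
                       summaries=summaries, paired=paired, concordance=conc,
                       profiles=profiles, walkability=walk,
                       scores=score_table(summaries))


# ---------------------------------------------------------------------------
# reliability ratings from two-rater audit sets

#: Unit-level measures and the audit kind that provides their targets.
RELIABILITY_MEASURES = {
    "destinations_land_use": ("route_side", "route_dlu"),
    "positive_streetscape": ("route_side", "route_streetscape"),
    "aesthetics_social": ("route_side", "route_aesthetics"),
    "segment_score": ("segment_side", "segment"),
}


def reliability_ratings(records: Sequence[AuditRecord],
                        scheme: ScoringScheme) -> dict[str, np.ndarray]:
    """Targets x 2 rating matrices per measure from a two-rater audit set.

    Route/segment measures use street sides as targets; the crossing score
    uses intersections (sum over connecting roads).  Units not assessed by
    both raters are skipped.
    """
    raters = sorted({r.auditor_id for r in records})
    if len(raters) != 2:
        raise ValueError(f"need exactly 2 raters, found {raters}")
    by_unit: dict[tuple[str, str, str], dict[str, AuditRecord]] = {}
    for r in records:
        by_unit.setdefault((r.unit_kind, r.school_id, r.unit_id), {})[r.auditor_id] = r

    out: dict[str, list[list[float]]] = {m: [] for m in RELIABILITY_MEASURES}
    cross: dict[tuple[str, str], list[list[float]]] = {}
    for (kind, school, unit_id), per_rater in sorted(by_unit.items()):
        if set(per_rater) != set(raters):
            continue
        if kind == "crossing":
            node = per_rater[raters[0]].intersection_id
            cross.setdefault((school, node), []).append(
                [unit_section_score(per_rater[a], scheme, "crossing")
                 for a in raters])
            continue
        for measure, (m_kind, section) in RELIABILITY_MEASURES.items():
            if kind == m_kind:
                out[measure].append(
                    [unit_section_score(per_rater[a], scheme, section)
                     for a in raters])
    matrices = {m: np.asarray(rows, dtype=float)
                for m, rows in out.items() if rows}
    if cross:
        matrices["crossing_score"] = np.asarray(
            [np.sum(rows, axis=0) for rows in cross.values()], dtype=float)
    return matrices
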