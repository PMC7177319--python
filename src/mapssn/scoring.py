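"""Hierarchical audit scoring: items -> sub-scales -> sections -> school.

Per audited unit, recoded item values are summed into valence sub-scales and
truncated at the sub-scale cap.  School-level section scores are unweighted
means over audited units in the requested side scope (odd / even /
combined); route and segment units are street sides, crossing units are
intersections (the per-intersection score is the sum over its
connecting-road crossing audits, so the crossing component is identical in
every side scope).  The overall grand score is the signed sum of school-level
sub-scale scores; cross-domain sub-scales sum school-level item averages
across sections.  Cul-de-sac audits are recorded but never scored.
"""
from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .audit_model import (AuditRecord, SchoolSummary, ScoringScheme, Subscale)
from .errors import MapsSNError

SIDE_SCOPES = ("odd", "even", "combined")

#: Section order used in reports; cul_de_sac never appears in scores.
SCORED_SECTIONS = ("route_dlu", "route_streetscape", "route_aesthetics",
                   "segment", "crossing")


@dataclass(frozen=True)
class SubscaleScore:
    """Raw and capped value of one sub-scale for one audited unit."""

    subscale: str
    raw_sum: int
    capped: int
    sign: int

    @property
    def signed(self) -> int:
        return self.sign * self.capped


@dataclass(frozen=True)
class CrossingScore:
    """Per-intersection crossing score: the sum over all connecting-road
    crossing audits at that intersection (side-free by construction)."""

    intersection_id: str
    value: float
    n_roads: int


def score_unit(record: AuditRecord, scheme: ScoringScheme) -> dict[str, SubscaleScore]:
    """Score one audit record against every sub-scale of its unit kind."""
    record.validate(scheme)
    out: dict[str, SubscaleScore] = {}
    for sub in scheme.subscales.values():
        members = [m for m in sub.items
                   if scheme.items[m].unit_kind == record.unit_kind]
        if not members:
            continue
        raw = sum(scheme.items[m].recoded(record.item_values[m]) for m in members)
        out[sub.name] = SubscaleScore(subscale=sub.name, raw_sum=raw,
                                      capped=min(raw, sub.cap), sign=sub.sign)
    return out


def unit_section_score(record: AuditRecord, scheme: ScoringScheme,
                       section: str) -> float:
    """Signed sum of the record's capped sub-scale scores in one section."""
    scores = score_unit(record, scheme)
    return float(sum(s.signed for name, s in scores.items()
                     if scheme.subscales[name].scored
                     and scheme.subscales[name].section == section))


def crossing_scores(records: Iterable[AuditRecord],
                    scheme: ScoringScheme) -> list[CrossingScore]:
    """Aggregate connecting-road crossing audits to per-intersection scores."""
    by_node: dict[str, list[AuditRecord]] = defaultdict(list)
    for r in records:
        if r.unit_kind != "crossing":
            raise MapsSNError(f"unit {r.unit_id}: not a crossing audit")
        by_node[r.intersection_id].append(r)
    out = []
    for node in sorted(by_node):
        recs = by_node[node]
        total = sum(unit_section_score(r, scheme, "crossing") for r in recs)
        out.append(CrossingScore(intersection_id=node, value=float(total),
                                 n_roads=len(recs)))
    return out


def _in_scope(record: AuditRecord, side_scope: str) -> bool:
    if record.unit_kind in ("crossing", "cul_de_sac"):
        return True  # side-free units belong to every scope
    if side_scope == "combined":
        return True
    return record.parity == side_scope


def aggregate_school(records: Iterable[AuditRecord], scheme: ScoringScheme,
                     side_scope: str = "combined",
                     school_id: str | None = None) -> SchoolSummary:
    """School-level summary over audited units in one side scope.

    Section scores are unweighted means of per-unit signed section scores
    (per intersection for crossings).  The grand score is the sum of signed
    school-level sub-scale means; cross-domain scores sum school-level item
    averages over the member lists.  A section with no audited unit in scope
    is reported missing and the grand score flagged incomplete — never a
    silent zero.
    """
    if side_scope not in SIDE_SCOPES:
        raise MapsSNError(f"unknown side_scope {side_scope!r}")
    records = [r for r in records if _in_scope(r, side_scope)]
    if not records:
        raise MapsSNError("no audit records in scope")
    if school_id is None:
        school_id = records[0].school_id

    route_seg = [r for r in records if r.unit_kind in ("route_side", "segment_side")]
    crossings = [r for r in records if r.unit_kind == "crossing"]

    # per-unit signed sub-scale values, then school-level means
    sub_values: dict[str, list[float]] = defaultdict(list)
    for r in route_seg:
        for name, s in score_unit(r, scheme).items():
            if scheme.subscales[name].scored:
                sub_values[name].append(float(s.capped))
    # crossing sub-scales aggregate per intersection (sum over roads)
    cross_by_node: dict[str, dict[str, float]] = defaultdict(lambda: defaultdict(float))
    for r in crossings:
        for name, s in score_unit(r, scheme).items():
            if scheme.subscales[name].scored:
                cross_by_node[r.intersection_id][name] += float(s.capped)
    for node_scores in cross_by_node.values():
        for name, val in node_scores.items():
            sub_values[name].append(val)

    sub_means = {name: fmean(vals) for name, vals in sub_values.items()}

    section_scores: dict[str, float] = {}
    missing: list[str] = []
    for section in SCORED_SECTIONS:
        subs = [s for s in scheme.scored_subscales() if s.section == section]
        vals = [s.sign * sub_means[s.name] for s in subs if s.name in sub_means]
        if vals:
            section_scores[section] = float(sum(vals))
        else:
            missing.append(section)

    incomplete = bool(missing)
    grand = None
    if not incomplete:
        grand = float(sum(s.sign * sub_means[s.name]
                          for s in scheme.scored_subscales()
                          if s.name in sub_means))
        if grand > scheme.grand_max:
            warnings.warn(
                f"school {school_id}: grand score {grand:.1f} exceeds the"
                f" per-unit scale maximum {scheme.grand_max}", stacklevel=2)

    # cross-domain: school-level item averages summed over member lists
    item_values: dict[str, list[float]] = defaultdict(list)
    for r in route_seg + crossings:
        for item_name, raw in r.item_values.items():
            item_values[item_name].append(
                float(scheme.items[item_name].recoded(raw)))
    cross_scores = {}
    for cd in scheme.cross_domain.values():
        present = [m for m in cd.items if m in item_values]
        if present:
            cross_scores[cd.name] = float(sum(fmean(item_values[m])
                                              for m in present))

    n_units = {"route_side": sum(1 for r in records if r.unit_kind == "route_side"),
               "segment_side": sum(1 for r in records if r.unit_kind == "segment_side"),
               "intersections": len(cross_by_node),
               "crossing_audits": len(crossings),
               "cul_de_sac": sum(1 for r in records if r.unit_kind == "cul_de_sac")}

    return SchoolSummary(school_id=school_id, side_scope=side_scope,
                         section_scores=section_scores,
                         cross_domain_scores=cross_scores,
                         grand_score=grand, n_units=n_units,
                         incomplete=incomplete,
                         missing_sections=tuple(missing))


#: Measures reported per school in concordance and score tables.
MEASURES = ("grand_score",
            "pedestrian_infrastructure", "pedestrian_design",
            "bicycle_facilities",
            "destinations_land_use", "positive_streetscape",
            "aesthetics_social", "segment_score", "crossing_score")

_SECTION_MEASURE = {"destinations_land_use": "route_dlu",
                    "positive_streetscape": "route_streetscape",
                    "aesthetics_social": "route_aesthetics",
                    "segment_score": "segment",
                    "crossing_score": "crossing"}


def summary_measures(summary: SchoolSummary) -> dict[str, float | None]:
    """Flatten a SchoolSummary into the standard report measures."""
    out: dict[str, float | None] = {"grand_score": summary.grand_score}
    for cd in ("pedestrian_infrastructure", "pedestrian_design",
               "bicycle_facilities"):
        out[cd] = summary.cross_domain_scores.get(cd)
    for measure, section in _SECTION_MEASURE.items():
        out[measure] = summary.section_scores.get(section)
    return out


def score_table(summaries: Iterable[SchoolSummary]) -> pd.DataFrame:
    """Wide score table: one row per (school, side_scope)."""
    rows = []
    for s in summaries:
        row = {"school_id": s.school_id, "side_scope": s.side_scope}
        row.update(summary_measures(s))
        rows.append(row)
    return pd.DataFrame(rows)


def concordance_inputs(summaries: Iterable[SchoolSummary]) -> pd.DataFrame:
    """Paired odd-vs-even score table, one row per school.

    Schools missing either side scope are dropped with a warning.  Columns
    are ``<measure>_odd`` / ``<measure>_even``; the crossing measure is
    intentionally identical across sides (shared crossing data).
    """
    by_school: dict[str, dict[str, SchoolSummary]] = defaultdict(dict)
    for s in summaries:
        by_school[s.school_id][s.side_scope] = s
    rows = []
    for school in sorted(by_school):
        scopes = by_school[school]
        if "odd" not in scopes or "even" not in scopes:
            warnings.warn(f"school {school}: missing a side scope, dropped",
                          stacklevel=2)
            continue
        row: dict[str, object] = {"school_id": school}
        for scope in ("odd", "even"):
            for measure, val in summary_measures(scopes[scope]).items():
                row[f"{measure}_{scope}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
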