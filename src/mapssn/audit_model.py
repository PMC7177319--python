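"""Domain types for school-neighbourhood audits and their scoring scheme.

A streetscape audit walks every street segment in a school's catchment and
records ordinal item values (presence/quality of sidewalks, crossings,
destinations, aesthetics, ...) for four kinds of audited unit:

* ``route_side``    — one side (odd/even house numbers) of a street segment,
                      assessed for destinations, streetscape and aesthetics;
* ``segment_side``  — the same side, assessed for street-layout features;
* ``crossing``      — one connecting road at an intersection with >= 3 legs;
* ``cul_de_sac``    — a cul-de-sac, amenities only (never scored).

The :class:`ScoringScheme` maps items to valence sub-scales, sub-scales to
sections, and defines three cross-domain sub-scales (pedestrian
infrastructure, pedestrian design, bicycle facilities) whose members are
drawn from several sections.  The packaged default scheme reproduces the
published scale maxima: overall grand score 210 points and cross-domain
maxima 27 / 22 / 11.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import AuditValidationError, SchemaError, SchemeConsistencyError

UNIT_KINDS = ("route_side", "segment_side", "crossing", "cul_de_sac")
SECTIONS = ("route_dlu", "route_streetscape", "route_aesthetics",
            "segment", "crossing", "cul_de_sac")

#: CSV columns that identify a record; everything else must be an item name.
KEY_COLUMNS = ("school_id", "unit_kind", "unit_id", "auditor_id", "audit_date")


# ---------------------------------------------------------------------------
# sampling-frame types

@dataclass(frozen=True)
class StreetSegment:
    """One inter-junction road piece inside (or crossing) a buffer zone.

    Identifier codes follow the compound convention
    ``school.street.segment`` with a side suffix ``O``/``E`` added at the
    :class:`StreetSide` level.
    """

    segment_id: str
    school_id: str
    length_m: float
    endpoint_nodes: tuple[str, str]
    residences_odd: int = 0
    residences_even: int = 0
    coverage_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.length_m <= 0:
            raise ValueError(f"segment {self.segment_id}: length_m must be > 0")
        if not (0.0 < self.coverage_fraction <= 1.0):
            raise ValueError(
                f"segment {self.segment_id}: coverage_fraction must be in (0, 1]")
        if min(self.residences_odd, self.residences_even) < 0:
            raise ValueError("residence counts must be >= 0")

    @property
    def residences_total(self) -> int:
        return self.residences_odd + self.residences_even

    def sides(self) -> tuple["StreetSide", "StreetSide"]:
        return (StreetSide(self.segment_id, "odd"),
                StreetSide(self.segment_id, "even"))


@dataclass(frozen=True)
class StreetSide:
    """One of exactly two sides of a street segment, by address parity."""

    segment_id: str
    parity: str  # "odd" | "even"

    def __post_init__(self) -> None:
        if self.parity not in ("odd", "even"):
            raise ValueError(f"parity must be odd/even, got {self.parity!r}")

    @property
    def side_id(self) -> str:
        return f"{self.segment_id}.{'O' if self.parity == 'odd' else 'E'}"


@dataclass(frozen=True)
class Intersection:
    """A junction with >= 3 connecting roads (degree-2 nodes are 'false'
    intersections left over from line splitting and are never audited)."""

    node_id: str
    connecting_roads: tuple[str, ...]
    school_id: str = ""

    def __post_init__(self) -> None:
        if len(self.connecting_roads) < 3:
            raise ValueError(
                f"intersection {self.node_id}: needs >= 3 connecting roads")

    @property
    def degree(self) -> int:
        return len(self.connecting_roads)


def side_parity(unit_id: str) -> str | None:
    """Parity encoded in a unit identifier's ``.O``/``.E`` suffix."""
    if unit_id.endswith(".O"):
        return "odd"
    if unit_id.endswith(".E"):
        return "even"
    return None


def crossing_intersection(unit_id: str) -> str:
    """Intersection id from a crossing unit id ``<intersection>:<road>``."""
    return unit_id.split(":", 1)[0]


# ---------------------------------------------------------------------------
# scoring scheme

@dataclass(frozen=True)
class Item:
    """A single audit item: raw integer range plus an optional recode map
    turning raw field codes into scored points."""

    name: str
    unit_kind: str
    lo: int
    hi: int
    recode: Mapping[int, int] | None = None
    cap: int | None = None

    def __post_init__(self) -> None:
        if self.unit_kind not in UNIT_KINDS:
            raise SchemeConsistencyError(
                f"item {self.name}: unknown unit_kind {self.unit_kind!r}")
        if self.lo > self.hi:
            raise SchemeConsistencyError(f"item {self.name}: empty range")
        if self.recode is not None:
            missing = [v for v in range(self.lo, self.hi + 1) if v not in self.recode]
            if missing:
                raise SchemeConsistencyError(
                    f"item {self.name}: recode map misses raw values {missing}")

    def in_range(self, raw: int) -> bool:
        return self.lo <= raw <= self.hi

    def recoded(self, raw: int) -> int:
        if not self.in_range(raw):
            raise AuditValidationError(
                f"item {self.name}: raw value {raw} outside [{self.lo}, {self.hi}]")
        pts = self.recode[raw] if self.recode is not None else raw
        if self.cap is not None:
            pts = min(pts, self.cap)
        return pts

    @property
    def best_points(self) -> int:
        """Highest attainable recoded value (before any sub-scale cap)."""
        return max(self.recoded(v) for v in range(self.lo, self.hi + 1))

    @property
    def worst_points(self) -> int:
        return min(self.recoded(v) for v in range(self.lo, self.hi + 1))

    @property
    def best_raw(self) -> int:
        return max(range(self.lo, self.hi + 1), key=self.recoded)

    @property
    def worst_raw(self) -> int:
        return min(range(self.lo, self.hi + 1), key=self.recoded)


@dataclass(frozen=True)
class Subscale:
    name: str
    section: str
    valence: str  # "positive" | "negative"
    cap: int
    items: tuple[str, ...]
    scored: bool = True

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise SchemeConsistencyError(
                f"subscale {self.name}: unknown section {self.section!r}")
        if self.valence not in ("positive", "negative"):
            raise SchemeConsistencyError(
                f"subscale {self.name}: valence must be positive/negative")

    @property
    def sign(self) -> int:
        return 1 if self.valence == "positive" else -1


@dataclass(frozen=True)
class CrossDomain:
    name: str
    max_points: int
    items: tuple[str, ...]


@dataclass(frozen=True)
class ScoringScheme:
    """Items -> valence sub-scales -> sections, plus cross-domain lists.

    Validated on construction: every item belongs to exactly one sub-scale,
    every declared maximum is achieved exactly by best-case scoring, and the
    signed best-case sum over scored sub-scales equals ``grand_max``.
    """

    name: str
    grand_max: int
    items: Mapping[str, Item]
    subscales: Mapping[str, Subscale]
    cross_domain: Mapping[str, CrossDomain]

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        owner: dict[str, str] = {}
        for sub in self.subscales.values():
            for item_name in sub.items:
                if item_name not in self.items:
                    raise SchemeConsistencyError(
                        f"subscale {sub.name}: unknown item {item_name!r}")
                if item_name in owner:
                    raise SchemeConsistencyError(
                        f"item {item_name!r} belongs to both {owner[item_name]!r}"
                        f" and {sub.name!r}")
                owner[item_name] = sub.name
                item = self.items[item_name]
                kinds = {self.items[m].unit_kind for m in sub.items}
                if len(kinds) > 1:
                    raise SchemeConsistencyError(
                        f"subscale {sub.name}: mixes unit kinds {sorted(kinds)}")
        orphans = set(self.items) - set(owner)
        if orphans:
            raise SchemeConsistencyError(
                f"items assigned to no sub-scale: {sorted(orphans)}")

        grand = self.best_case_grand_score()
        if grand != self.grand_max:
            raise SchemeConsistencyError(
                f"best-case grand score {grand} != declared grand_max {self.grand_max}")
        for cd in self.cross_domain.values():
            for item_name in cd.items:
                if item_name not in self.items:
                    raise SchemeConsistencyError(
                        f"cross-domain {cd.name}: unknown item {item_name!r}")
            best = self.best_case_cross_domain(cd.name)
            if best != cd.max_points:
                raise SchemeConsistencyError(
                    f"cross-domain {cd.name}: achievable max {best} != declared"
                    f" {cd.max_points}")

    # -- best/worst-case scale arithmetic --------------------------------
    def subscale_of(self, item_name: str) -> Subscale:
        for sub in self.subscales.values():
            if item_name in sub.items:
                return sub
        raise KeyError(item_name)

    def items_for(self, unit_kind: str) -> list[Item]:
        return [it for it in self.items.values() if it.unit_kind == unit_kind]

    def scored_subscales(self) -> list[Subscale]:
        return [s for s in self.subscales.values() if s.scored]

    def best_case_subscale(self, name: str) -> int:
        """Capped sub-scale value when every member item is at its best
        recode (for negative valence: at its least-penalising recode)."""
        sub = self.subscales[name]
        if sub.valence == "positive":
            raw_sum = sum(self.items[m].best_points for m in sub.items)
        else:
            raw_sum = sum(self.items[m].worst_points for m in sub.items)
        return min(raw_sum, sub.cap)

    def worst_case_subscale(self, name: str) -> int:
        sub = self.subscales[name]
        if sub.valence == "positive":
            raw_sum = sum(self.items[m].worst_points for m in sub.items)
        else:
            raw_sum = sum(self.items[m].best_points for m in sub.items)
        return min(raw_sum, sub.cap)

    def best_case_grand_score(self) -> int:
        """Signed sum of capped sub-scale scores at best-case item values
        (210 for the packaged default scheme)."""
        return sum(s.sign * self.best_case_subscale(s.name)
                   for s in self.scored_subscales())

    def worst_case_grand_score(self) -> int:
        return sum(s.sign * self.worst_case_subscale(s.name)
                   for s in self.scored_subscales())

    def best_case_cross_domain(self, name: str) -> int:
        """Cross-domain sub-scale value for a school whose every member item
        averages its best recode (27 / 22 / 11 for the default scheme)."""
        cd = self.cross_domain[name]
        return sum(self.items[m].best_points for m in cd.items)


def _parse_scheme(doc: Mapping) -> ScoringScheme:
    try:
        items = {}
        for name, meta in doc["items"].items():
            lo, hi = meta["range"]
            recode = meta.get("recode")
            if recode is not None:
                recode = {int(k): int(v) for k, v in recode.items()}
            items[name] = Item(name=name, unit_kind=meta["unit_kind"],
                               lo=int(lo), hi=int(hi), recode=recode,
                               cap=meta.get("cap"))
        subscales = {}
        for name, meta in doc["subscales"].items():
            subscales[name] = Subscale(
                name=name, section=meta["section"], valence=meta["valence"],
                cap=int(meta["cap"]), items=tuple(meta["items"]),
                scored=bool(meta.get("scored", True)))
        cross = {}
        for name, meta in doc.get("cross_domain", {}).items():
            cross[name] = CrossDomain(name=name, max_points=int(meta["max"]),
                                      items=tuple(meta["items"]))
    except KeyError as exc:  # missing mandatory key
        raise SchemaError(f"scheme configuration misses key {exc}") from exc
    return ScoringScheme(name=doc.get("name", "unnamed"),
                         grand_max=int(doc["grand_max"]),
                         items=items, subscales=subscales, cross_domain=cross)


def load_scheme(path: str | Path | None = None) -> ScoringScheme:
    """Load a scoring scheme from YAML; ``None`` loads the packaged default."""
    if path is None:
        text = resources.files("mapssn.schemes").joinpath(
            "default_scheme.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise SchemaError("scheme configuration is not a mapping")
    return _parse_scheme(doc)


# ---------------------------------------------------------------------------
# audit records and CSV I/O

@dataclass(frozen=True)
class AuditRecord:
    """Item values recorded for one audited unit by one auditor.

    ``unit_id`` conventions: ``school.street.segment.O|E`` for route/segment
    sides, ``<intersection>:<road>`` for crossings, a plain identifier for
    cul-de-sacs.
    """

    unit_kind: str
    unit_id: str
    school_id: str
    item_values: Mapping[str, int]
    auditor_id: str = "A1"
    audit_date: _dt.date = _dt.date(2017, 9, 1)

    def __post_init__(self) -> None:
        if self.unit_kind not in UNIT_KINDS:
            raise AuditValidationError(f"unknown unit_kind {self.unit_kind!r}")

    @property
    def parity(self) -> str | None:
        return side_parity(self.unit_id)

    @property
    def intersection_id(self) -> str | None:
        if self.unit_kind != "crossing":
            return None
        return crossing_intersection(self.unit_id)

    def validate(self, scheme: ScoringScheme) -> None:
        expected = {it.name for it in scheme.items_for(self.unit_kind)}
        for name, raw in self.item_values.items():
            if name not in expected:
                raise AuditValidationError(
                    f"unit {self.unit_id}: item {name!r} is not a"
                    f" {self.unit_kind} item in scheme {scheme.name!r}")
            if not scheme.items[name].in_range(int(raw)):
                item = scheme.items[name]
                raise AuditValidationError(
                    f"unit {self.unit_id}: item {name!r} value {raw} outside"
                    f" [{item.lo}, {item.hi}]")
        missing = expected - set(self.item_values)
        if missing:
            raise AuditValidationError(
                f"unit {self.unit_id}: missing items {sorted(missing)}")


def read_audits(path: str | Path, scheme: ScoringScheme) -> list[AuditRecord]:
    """Read an audit table (CSV, one row per audited unit) and validate every
    value against the scheme.

    Columns are the key columns plus item names; item cells not applicable
    to a row's unit kind are left blank.  Unknown columns raise
    :class:`SchemaError`; out-of-range values raise
    :class:`AuditValidationError` naming row and item.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_keys = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing_keys:
        raise SchemaError(f"audit table misses key columns {missing_keys}")
    unknown = [c for c in df.columns
               if c not in KEY_COLUMNS and c not in scheme.items]
    if unknown:
        raise SchemaError(f"unknown item columns {unknown}")

    records: list[AuditRecord] = []
    for idx, row in df.iterrows():
        kind = row["unit_kind"]
        if kind not in UNIT_KINDS:
            raise AuditValidationError(f"row {idx}: unknown unit_kind {kind!r}")
        values: dict[str, int] = {}
        for item in scheme.items_for(kind):
            cell = row.get(item.name, "")
            if cell == "":
                raise AuditValidationError(
                    f"row {idx}: missing value for item {item.name!r}")
            try:
                raw = int(cell)
            except ValueError as exc:
                raise AuditValidationError(
                    f"row {idx}: item {item.name!r} value {cell!r} is not an"
                    " integer") from exc
            if not item.in_range(raw):
                raise AuditValidationError(
                    f"row {idx}: item {item.name!r} value {raw} outside"
                    f" [{item.lo}, {item.hi}]")
            values[item.name] = raw
        rec = AuditRecord(unit_kind=kind, unit_id=row["unit_id"],
                          school_id=row["school_id"],
                          auditor_id=row["auditor_id"] or "A1",
                          audit_date=_dt.date.fromisoformat(row["audit_date"]),
                          item_values=values)
        rec.validate(scheme)
        records.append(rec)
    return records


def write_audits(records: Iterable[AuditRecord], path: str | Path,
                 scheme: ScoringScheme) -> None:
    """Write records to CSV; inverse of :func:`read_audits` up to column order."""
    records = list(records)
    item_cols = [name for name in scheme.items
                 if any(name in r.item_values for r in records)]
    rows = []
    for r in records:
        row = {"school_id": r.school_id, "unit_kind": r.unit_kind,
               "unit_id": r.unit_id, "auditor_id": r.auditor_id,
               "audit_date": r.audit_date.isoformat()}
        for c in item_cols:
            row[c] = r.item_values.get(c, "")
        rows.append(row)
    pd.DataFrame(rows, columns=list(KEY_COLUMNS) + item_cols).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# school-level summaries

@dataclass
class SchoolSummary:
    """Per-school mean section scores, cross-domain scores and grand score
    for one side scope (odd / even / combined)."""

    school_id: str
    side_scope: str
    section_scores: dict[str, float] = field(default_factory=dict)
    cross_domain_scores: dict[str, float] = field(default_factory=dict)
    grand_score: float | None = None
    n_units: dict[str, int] = field(default_factory=dict)
    incomplete: bool = False
    missing_sections: tuple[str, ...] = ()
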