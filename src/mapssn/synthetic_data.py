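"""Seeded generators for street grids, residences, land use and audits.

The generator emulates the study conditions of a small coastal city: twelve
secondary-school neighbourhoods, gridded residential street networks with
~100 m blocks, addresses numbered odd/even by street side, a five-category
land-use mosaic dominated by residential use, and ordinal audit items whose
odd- and even-side values share a latent Gaussian with controllable
correlation.  A second rater is the first plus discretised noise, so the
implied inter-rater ICC is controlled by the noise standard deviation.

Every output is a plain package type (StreetNetwork, AuditRecord, ...) in
exactly the formats the readers consume; identical seeds give identical
output, with independent sub-streams per school.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from shapely.geometry import Polygon

from .audit_model import AuditRecord, Intersection, ScoringScheme, StreetSegment
from .errors import MapsSNError
from .network_buffer import StreetNetwork

DEFAULT_LAND_USE_MIX = {"residential": 0.60, "commercial": 0.15,
                        "industrial": 0.05, "tertiary_campus": 0.05,
                        "open_space": 0.15}


@dataclass(frozen=True)
class CityConfig:
    """Study conditions for the synthetic city.

    Defaults emulate the published study context: 12 schools, ~100 m street
    blocks, about three residences per 100 m of street (both sides), a
    residential-dominated land-use mix, modest item levels, strong
    between-side correlation and small rater noise.
    """

    n_schools: int = 12
    grid_rows: int = 7
    grid_cols: int = 7
    edge_length_m: float = 100.0
    edge_length_jitter: float = 0.10  # relative sd of block-length jitter
    residences_per_100m_per_side: float = 1.5
    land_use_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAND_USE_MIX))
    parcel_depth_m: float = 50.0
    item_mean_level: float = 0.25  # mean item value as a fraction of its max
    crossing_item_mean_level: float = 0.10  # crossing infrastructure is sparse
    between_side_rho: float = 0.9
    rater_noise_sd: float = 0.3
    include_cul_de_sacs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.between_side_rho <= 1.0):
            raise MapsSNError("between_side_rho must lie in [-1, 1]")
        if self.rater_noise_sd < 0 or self.residences_per_100m_per_side < 0:
            raise MapsSNError("intensities must be >= 0")
        if min(self.grid_rows, self.grid_cols) < 2 or self.n_schools < 1:
            raise MapsSNError("need a grid of >= 2x2 nodes and >= 1 school")
        if not (0.0 < self.item_mean_level < 1.0):
            raise MapsSNError("item_mean_level must lie in (0, 1)")


def school_rng(config: CityConfig, school_index: int,
               stream: int = 0) -> np.random.Generator:
    """Independent, reproducible sub-stream for one school."""
    return np.random.default_rng([config.seed, school_index, stream])


def school_ids(config: CityConfig) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(config.n_schools)]


# ---------------------------------------------------------------------------
# city geometry

def generate_city(config: CityConfig) -> tuple[StreetNetwork, dict[str, tuple[float, float]]]:
    """Build the city street network and one school point per neighbourhood.

    Each school gets its own grid of streets (rows and columns emitted as
    single polylines, so network construction exercises junction
    splitting), spatially offset so neighbourhoods do not interleave.
    Addresses are placed along edges with odd numbers on one side and even
    on the other; land-use parcels tile a corridor strip on both sides of
    every street.
    """
    lines: list[tuple[str, list[tuple[float, float]]]] = []
    addresses: list[tuple[tuple[float, float], int]] = []
    parcels: list[tuple[Polygon, str]] = []
    schools: dict[str, tuple[float, float]] = {}
    categories = list(config.land_use_mixture)
    cat_p = np.asarray([config.land_use_mixture[c] for c in categories], float)
    if cat_p.sum() <= 0:
        raise MapsSNError("land-use mixture must have positive mass")
    cat_p = cat_p / cat_p.sum()

    span = (config.grid_cols + 4) * config.edge_length_m
    for s, school in enumerate(school_ids(config)):
        rng = school_rng(config, s)
        x0 = s * span
        # jittered grid line positions (shared by rows and columns)
        xs = x0 + np.cumsum(np.concatenate([[0.0], rng.normal(
            config.edge_length_m,
            config.edge_length_jitter * config.edge_length_m,
            config.grid_cols - 1).clip(min=20.0)]))
        ys = np.cumsum(np.concatenate([[0.0], rng.normal(
            config.edge_length_m,
            config.edge_length_jitter * config.edge_length_m,
            config.grid_rows - 1).clip(min=20.0)]))
        for r in range(config.grid_rows):
            lines.append((f"{school}.R{r}", [(x, ys[r]) for x in xs]))
        for c in range(config.grid_cols):
            lines.append((f"{school}.C{c}", [(xs[c], y) for y in ys]))
        schools[school] = (float(xs[config.grid_cols // 2]),
                           float(ys[config.grid_rows // 2]))

    net = StreetNetwork.from_lines(lines)

    # addresses and land use, per school sub-stream
    by_school: dict[str, list] = {s: [] for s in schools}
    for eid, edge in net.edges.items():
        by_school[eid.split(".", 1)[0]].append(edge)
    next_number: dict[str, int] = {}
    for s, school in enumerate(school_ids(config)):
        rng = school_rng(config, s, stream=1)
        for edge in by_school[school]:
            line = edge.line
            (x1, y1), (x2, y2) = edge.coords[0], edge.coords[-1]
            ux, uy = (x2 - x1) / edge.length_m, (y2 - y1) / edge.length_m
            nx_, ny_ = -uy, ux  # unit normal
            for side, parity_start in (("odd", 1), ("even", 2)):
                lam = config.residences_per_100m_per_side * edge.length_m / 100.0
                n_res = int(rng.poisson(lam))
                offs = np.sort(rng.uniform(0.0, edge.length_m, n_res))
                sign = 1.0 if side == "odd" else -1.0
                for t in offs:
                    p = line.interpolate(float(t))
                    pt = (p.x + sign * 5.0 * nx_, p.y + sign * 5.0 * ny_)
                    key = (edge.edge_id, side)
                    num = next_number.get(key, parity_start)
                    next_number[key] = num + 2
                    addresses.append((pt, num))
            for sign in (1.0, -1.0):  # land-use strip on each side
                cat = categories[int(rng.choice(len(categories), p=cat_p))]
                quad = [(x1 + sign * 2 * nx_, y1 + sign * 2 * ny_),
                        (x2 + sign * 2 * nx_, y2 + sign * 2 * ny_),
                        (x2 + sign * config.parcel_depth_m * nx_,
                         y2 + sign * config.parcel_depth_m * ny_),
                        (x1 + sign * config.parcel_depth_m * nx_,
                         y1 + sign * config.parcel_depth_m * ny_)]
                parcels.append((Polygon(quad), cat))

    net.add_addresses(addresses)
    net.land_use_parcels = parcels
    return net, schools


# ---------------------------------------------------------------------------
# audit generation

def _discretize(u: np.ndarray, lo: int, hi: int, mean_level: float) -> np.ndarray:
    """Map latent uniforms to the item's integer range via the quantile
    function of a Binomial(hi-lo, mean_level) — exact latent correlation
    control with ordinal output."""
    if hi == lo:
        return np.full(u.shape, lo)
    return lo + stats.binom.ppf(u, hi - lo, mean_level).astype(int)


def generate_audits(segments: Sequence[StreetSegment],
                    intersections: Sequence[Intersection],
                    scheme: ScoringScheme,
                    config: CityConfig,
                    school_index: int = 0,
                    n_raters: int = 1) -> list[AuditRecord]:
    """Audit records for one school's sampling frame.

    Per segment, each route/segment item draws a correlated latent pair
    (odd, even) with correlation ``between_side_rho``; crossing audits are
    generated per connecting road without sides; rater 2 equals rater 1
    plus rounded Gaussian noise clipped to the item range.
    """
    if n_raters not in (1, 2):
        raise MapsSNError("n_raters must be 1 or 2")
    rng = school_rng(config, school_index, stream=2)
    rho = config.between_side_rho
    records: list[AuditRecord] = []
    n_seg = len(segments)

    def add_record(kind: str, unit_id: str, school_id: str,
                   values: dict[str, int], auditor: str) -> None:
        records.append(AuditRecord(unit_kind=kind, unit_id=unit_id,
                                   school_id=school_id, auditor_id=auditor,
                                   item_values=values))

    def noisy(values: dict[str, int]) -> dict[str, int]:
        out = {}
        for name, v in values.items():
            item = scheme.items[name]
            shift = int(np.rint(rng.normal(0.0, config.rater_noise_sd)))
            out[name] = int(np.clip(v + shift, item.lo, item.hi))
        return out

    # route/segment sides: one correlated latent pair per (item, segment)
    for kind in ("route_side", "segment_side"):
        items = scheme.items_for(kind)
        if not items or n_seg == 0:
            continue
        drawn: dict[str, np.ndarray] = {}
        for item in items:
            z = rng.multivariate_normal(
                [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n_seg)
            drawn[item.name] = _discretize(stats.norm.cdf(z), item.lo,
                                           item.hi, config.item_mean_level)
        for i, seg in enumerate(segments):
            for j, side in enumerate(seg.sides()):  # odd then even
                values = {name: int(v[i, j]) for name, v in drawn.items()}
                add_record(kind, side.side_id, seg.school_id, values, "A1")
                if n_raters == 2:
                    add_record(kind, side.side_id, seg.school_id,
                               noisy(values), "A2")

    # crossings: one audit per connecting road, no sides
    units = [(inter, road) for inter in intersections
             for road in inter.connecting_roads]
    cross_items = scheme.items_for("crossing")
    if units and cross_items:
        drawn = {item.name: _discretize(rng.uniform(size=len(units)),
                                        item.lo, item.hi,
                                        config.crossing_item_mean_level)
                 for item in cross_items}
        for i, (inter, road) in enumerate(units):
            values = {name: int(v[i]) for name, v in drawn.items()}
            uid = f"{inter.node_id}:{road}"
            add_record("crossing", uid, inter.school_id, values, "A1")
            if n_raters == 2:
                add_record("crossing", uid, inter.school_id, noisy(values), "A2")

    if config.include_cul_de_sacs:
        cds_items = scheme.items_for("cul_de_sac")
        if cds_items and segments:
            school_id = segments[0].school_id
            values = {it.name: int(rng.integers(it.lo, it.hi + 1))
                      for it in cds_items}
            add_record("cul_de_sac", f"{school_id}.CDS1", school_id, values, "A1")
            if n_raters == 2:
                add_record("cul_de_sac", f"{school_id}.CDS1", school_id,
                           noisy(values), "A2")
    return records


# ---------------------------------------------------------------------------
# statistical micro-generators (parameter-recovery checks)

def correlated_pairs(n: int, rho: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """n bivariate-normal pairs with correlation rho (unit marginals)."""
    if not (-1.0 <= rho <= 1.0):
        raise MapsSNError("rho must lie in [-1, 1]")
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    return z[:, 0], z[:, 1]


def two_rater_ratings(n_targets: int, target_sd: float, noise_sd: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Continuous two-rater ratings with known variance components.

    The analytic single-rater agreement ICC is
    ``target_sd**2 / (target_sd**2 + noise_sd**2)``.
    """
    truth = rng.normal(0.0, target_sd, size=n_targets)
    return np.column_stack([truth + rng.normal(0.0, noise_sd, n_targets),
                            truth + rng.normal(0.0, noise_sd, n_targets)])


def analytic_icc(target_sd: float, noise_sd: float) -> float:
    return target_sd ** 2 / (target_sd ** 2 + noise_sd ** 2)
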