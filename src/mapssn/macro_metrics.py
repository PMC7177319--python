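"""Macro-scale neighbourhood measures: densities, land-use mix, walkability.

The denominator area is a corridor polygon: the union of fixed-radius
buffers (default 95 m) around the covered street intervals of the network
service area.  Land-use mix is the Shannon entropy of category area
proportions normalised by ln(k) over the k = 5 configured categories
(residential, commercial, industrial, tertiary campus, open space), so 0
means a single use and 1 a perfectly even mix.  The walkability index of a
school is the sum of its within-sample z-scores of intersection density,
residential density and land-use mix; by construction the index averages 0
over the sample of schools.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import substring, unary_union

from .errors import InsufficientDataError, MapsSNError, UndefinedStatisticError
from .network_buffer import BufferZone, StreetNetwork

LAND_USE_CATEGORIES = ("residential", "commercial", "industrial",
                       "tertiary_campus", "open_space")

#: Buffer radius around road centrelines for the corridor polygon, metres.
DEFAULT_CORRIDOR_RADIUS_M = 95.0

_QUAD_SEGS = 64  # circular-arc resolution of shapely buffers


@dataclass
class MacroProfile:
    """Macro-scale profile of one school neighbourhood."""

    school_id: str
    area_km2: float
    n_junctions: int
    n_residences: int
    intersection_density: float  # junctions / km^2
    residential_density: float  # residences / km^2
    land_use_mix: float  # in [0, 1]
    walkability: float | None = None  # z-sum, filled in per sample

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise MapsSNError(f"school {self.school_id}: area must be > 0")
        if not (-1e-9 <= self.land_use_mix <= 1 + 1e-9):
            raise MapsSNError("land_use_mix must lie in [0, 1]")


def corridor_polygon(network: StreetNetwork, buffer: BufferZone,
                     corridor_radius_m: float = DEFAULT_CORRIDOR_RADIUS_M) -> Polygon:
    """Union of fixed-radius corridors around the covered edge intervals."""
    if corridor_radius_m <= 0:
        raise MapsSNError("corridor_radius_m must be > 0")
    parts = []
    for eid, intervals in buffer.covered_edges.items():
        line = network.edges[eid].line
        for a, b in intervals:
            parts.append(substring(line, a, b).buffer(
                corridor_radius_m, quad_segs=_QUAD_SEGS))
    if not parts:
        raise InsufficientDataError("empty buffer: corridor area undefined")
    return unary_union(parts)


def buffer_area(network: StreetNetwork, buffer: BufferZone,
                corridor_radius_m: float = DEFAULT_CORRIDOR_RADIUS_M) -> float:
    """Corridor area in km^2."""
    return corridor_polygon(network, buffer, corridor_radius_m).area / 1e6


def intersection_density(n_junctions: int, area_km2: float) -> float:
    if area_km2 <= 0:
        raise UndefinedStatisticError("density undefined for zero area")
    return n_junctions / area_km2


def residential_density(n_residences: int, area_km2: float) -> float:
    if area_km2 <= 0:
        raise UndefinedStatisticError("density undefined for zero area")
    return n_residences / area_km2


def land_use_mix(proportions: Sequence[float] | Mapping[str, float],
                 k: int | None = None) -> float:
    """Normalised Shannon entropy of land-use proportions.

    ``k`` defaults to the 5 configured categories regardless of how many are
    present (pass ``k=len(nonzero)`` for the present-categories variant).
    """
    if isinstance(proportions, Mapping):
        p = np.asarray([proportions.get(c, 0.0) for c in LAND_USE_CATEGORIES],
                       dtype=float)
    else:
        p = np.asarray(list(proportions), dtype=float)
    if (p < 0).any():
        raise MapsSNError("proportions must be >= 0")
    if abs(p.sum() - 1.0) > 1e-9:
        raise MapsSNError(f"proportions sum to {p.sum():.12f}, expected 1")
    if k is None:
        k = len(LAND_USE_CATEGORIES)
    if k < 2:
        raise MapsSNError("need k >= 2 categories")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return h / math.log(k)


def land_use_proportions(network: StreetNetwork,
                         corridor: Polygon) -> dict[str, float]:
    """Category area shares of land-use parcels clipped to the corridor."""
    areas = {c: 0.0 for c in LAND_USE_CATEGORIES}
    for poly, category in network.land_use_parcels:
        if category not in areas:
            raise MapsSNError(f"unknown land-use category {category!r}")
        areas[category] += poly.intersection(corridor).area
    total = sum(areas.values())
    if total <= 0:
        raise InsufficientDataError("no land-use parcel intersects the corridor")
    return {c: a / total for c, a in areas.items()}


def macro_profile(network: StreetNetwork, buffer: BufferZone,
                  n_junctions: int,
                  corridor_radius_m: float = DEFAULT_CORRIDOR_RADIUS_M) -> MacroProfile:
    """Compute one school's macro profile from its buffer zone.

    Residences are address points lying inside the corridor polygon (one
    residence per address point).
    """
    corridor = corridor_polygon(network, buffer, corridor_radius_m)
    area_km2 = corridor.area / 1e6
    from shapely.geometry import Point
    n_res = sum(1 for a in network.address_points
                if corridor.covers(Point(a.point)))
    if network.land_use_parcels:
        mix = land_use_mix(land_use_proportions(network, corridor))
    else:
        mix = 0.0
    return MacroProfile(school_id=buffer.school_id, area_km2=area_km2,
                        n_junctions=n_junctions, n_residences=n_res,
                        intersection_density=intersection_density(n_junctions, area_km2),
                        residential_density=residential_density(n_res, area_km2),
                        land_use_mix=mix)


def walkability(profiles: Sequence[MacroProfile]) -> pd.Series:
    """Composite walkability index per school: z(intersection density) +
    z(residential density) + z(land-use mix), sample sd (n-1).

    A component with zero variance contributes 0 for every school (logged).
    The returned indices are also written back onto the profiles.
    """
    if len(profiles) < 2:
        raise InsufficientDataError("walkability needs >= 2 schools")
    df = pd.DataFrame({
        "intersection_density": [p.intersection_density for p in profiles],
        "residential_density": [p.residential_density for p in profiles],
        "land_use_mix": [p.land_use_mix for p in profiles],
    }, index=[p.school_id for p in profiles])
    z = pd.DataFrame(0.0, index=df.index, columns=df.columns)
    for col in df.columns:
        sd = df[col].std(ddof=1)
        if sd == 0:
            warnings.warn(f"walkability component {col!r} has zero variance;"
                          " its z-score is 0 by convention", stacklevel=2)
        else:
            z[col] = (df[col] - df[col].mean()) / sd
    index = z.sum(axis=1)
    for p in profiles:
        p.walkability = float(index[p.school_id])
    return index


def profiles_table(profiles: Iterable[MacroProfile]) -> pd.DataFrame:
    rows = [{"school_id": p.school_id, "area_km2": p.area_km2,
             "n_junctions": p.n_junctions, "n_residences": p.n_residences,
             "intersection_density": p.intersection_density,
             "residential_density": p.residential_density,
             "land_use_mix": p.land_use_mix,
             "walkability": p.walkability} for p in profiles]
    return pd.DataFrame(rows)
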