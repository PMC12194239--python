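"""Island / zone geometry: the six coastal zones, point-in-zone queries,
depth strata, and the synthetic annular-sector zone set.

The six zones RC_A..RC_F ring the island pair and serve both as release
areas and recruitment targets.  Point-in-zone queries resolve boundary
points to the lowest zone id among the zones touching the point, which
makes the assignment a deterministic partition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, shape, mapping

from .errors import ValidationError

ZONE_IDS = ("RC_A", "RC_B", "RC_C", "RC_D", "RC_E", "RC_F")

#: metres per degree of latitude
M_PER_DEG = 6_371_000.0 * math.pi / 180.0

#: default island centre (lon, lat): Robinson Crusoe / Santa Clara area
DEFAULT_ISLAND_CENTER = (-78.85, -33.64)


@dataclass
class Zone:
    id: str
    polygon: Polygon

    def validate(self) -> None:
        if not self.polygon.is_valid or not self.polygon.is_simple:
            raise ValidationError(f"zone {self.id}: polygon is not simple/valid")
        if self.polygon.area <= 0:
            raise ValidationError(f"zone {self.id}: polygon has zero area")


@dataclass
class ZoneSet:
    """Ordered collection of labelled zones plus the island land polygon."""

    zones: list[Zone]
    island: Polygon | None = None
    _geoms: np.ndarray = dc_field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.validate()
        self._geoms = np.array([z.polygon for z in self.zones], dtype=object)

    def validate(self) -> None:
        ids = [z.id for z in self.zones]
        if len(set(ids)) != len(ids):
            raise ValidationError("zone ids must be unique")
        for z in self.zones:
            z.validate()
        for i, a in enumerate(self.zones):
            for b in self.zones[i + 1:]:
                inter = a.polygon.intersection(b.polygon)
                if inter.area > 1e-9 * min(a.polygon.area, b.polygon.area):
                    raise ValidationError(f"zones {a.id} and {b.id} overlap")
        if self.island is not None:
            # coastal-ring property; tolerance ~2 km in degrees
            for z in self.zones:
                if z.polygon.distance(self.island) > 0.02:
                    raise ValidationError(f"zone {z.id} is not adjacent to the island")

    @property
    def ids(self) -> list[str]:
        return [z.id for z in self.zones]

    def union(self):
        return shapely.unary_union([z.polygon for z in self.zones])


@dataclass(frozen=True)
class DepthStrata:
    """Bathymetric depth bins; half-open [lower, upper) so strata never overlap."""

    edges: tuple = (0.0, 50.0, 100.0, 150.0, 200.0)

    def __post_init__(self):
        if len(self.edges) < 2 or not all(
            a < b for a, b in zip(self.edges, self.edges[1:])
        ):
            raise ValidationError("strata edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        return [
            f"{int(a)}-{int(b)}" for a, b in zip(self.edges, self.edges[1:])
        ]


def depth_stratum(strata: DepthStrata, depth: float) -> str | None:
    """Label of the half-open stratum [lower, upper) containing ``depth``;
    None beyond the deepest edge."""
    if depth < 0:
        raise ValueError(f"depth must be non-negative, got {depth}")
    idx = np.searchsorted(strata.edges, depth, side="right") - 1
    if idx >= len(strata.edges) - 1:
        return None
    return strata.labels[idx]


def locate_zone(zones: ZoneSet, lon: float, lat: float) -> str | None:
    """Id of the zone containing the point, or None.

    Boundary points (including points on an edge shared by two zones)
    resolve to the lowest id among the touching zones.
    """
    p = Point(lon, lat)
    for z in zones.zones:  # id order => lowest-id tie-break
        if z.polygon.intersects(p):
            return z.id
    return None


def locate_zone_many(zones: ZoneSet, lon, lat) -> np.ndarray:
    """Vectorised :func:`locate_zone`: int zone index per point, -1 outside."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    out = np.full(lon.shape, -1, dtype=np.int64)
    for i, z in enumerate(zones.zones):
        undecided = out < 0
        if not undecided.any():
            break
        hit = shapely.intersects_xy(z.polygon, lon[undecided], lat[undecided])
        idx = np.flatnonzero(undecided)[hit]
        out[idx] = i
    return out


# -- synthetic geometry --------------------------------------------------


def _offset_point(center, bearing_deg, dist_km):
    lon0, lat0 = center
    east = dist_km * 1000.0 * math.sin(math.radians(bearing_deg))
    north = dist_km * 1000.0 * math.cos(math.radians(bearing_deg))
    return (
        lon0 + east / (M_PER_DEG * math.cos(math.radians(lat0))),
        lat0 + north / M_PER_DEG,
    )


def _circle(center, radius_km, n=90) -> Polygon:
    return Polygon(
        [_offset_point(center, b, radius_km) for b in np.linspace(0.0, 360.0, n, endpoint=False)]
    )


def synthetic_zoneset(
    island_center=DEFAULT_ISLAND_CENTER,
    island_radius_km: float = 8.0,
    ring_width_km: float = 8.0,
    arc_points: int = 24,
) -> ZoneSet:
    """Six equal-angle annular sectors around a circular island.

    Stands in for the unpublished real zone polygons: RC_A..RC_F run
    clockwise from north, each spanning 60 degrees of bearing between the
    island shore (``island_radius_km``) and ``island_radius_km +
    ring_width_km`` offshore.
    """
    if island_radius_km <= 0 or ring_width_km <= 0:
        raise ValidationError("island radius and ring width must be positive")
    r_in = island_radius_km
    r_out = island_radius_km + ring_width_km
    zones = []
    for i, zid in enumerate(ZONE_IDS):
        b0, b1 = 60.0 * i, 60.0 * (i + 1)
        bearings = np.linspace(b0, b1, arc_points)
        ring = [_offset_point(island_center, b, r_out) for b in bearings]
        ring += [_offset_point(island_center, b, r_in) for b in bearings[::-1]]
        zones.append(Zone(id=zid, polygon=Polygon(ring)))
    island = _circle(island_center, island_radius_km)
    return ZoneSet(zones=zones, island=island)


# -- GeoJSON I/O ---------------------------------------------------------


def write_zoneset_geojson(zones: ZoneSet, path) -> None:
    features = [
        {"type": "Feature", "properties": {"id": z.id}, "geometry": mapping(z.polygon)}
        for z in zones.zones
    ]
    if zones.island is not None:
        features.append(
            {"type": "Feature", "properties": {"id": "island"},
             "geometry": mapping(zones.island)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_zoneset_geojson(path) -> ZoneSet:
    with open(path) as fh:
        fc = json.load(fh)
    zones, island = [], None
    for feat in fc.get("features", []):
        zid = feat.get("properties", {}).get("id")
        geom = shape(feat["geometry"])
        if zid == "island":
            island = geom
        else:
            zones.append(Zone(id=zid, polygon=geom))
    zones.sort(key=lambda z: z.id)
    return ZoneSet(zones=zones, island=island)
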