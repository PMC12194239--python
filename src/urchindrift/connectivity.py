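"""Connectivity and retention indices over the larval recruitment window.

A particle recruits to the zone containing its position at the FIRST
snapshot whose particle age falls in the 110-120 day window (115 +/- 5
days: pods form within ~100 days and settlement takes about five), provided
it is still drifting at that snapshot.  The 6x6 release-zone x
recruitment-zone count matrix carries retention on its diagonal; source and
sink summaries are its row and column shares of all recruits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .ibm import ACTIVE, DAY_S, TrajectorySet
from .zones import ZoneSet, locate_zone_many

DEFAULT_WINDOW_DAYS = (110.0, 120.0)


def round_pct(x: float, ndigits: int = 2) -> float:
    """Percentage rounding with halves up, matching printed report precision."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConnectivityMatrix:
    """Release-zone x recruitment-zone recruit counts.

    ``counts[i, j]`` = particles released in zone i that recruited to zone j;
    unrecruited particles appear in no cell.
    """

    counts: np.ndarray  # (n_zones, n_zones) int
    zone_ids: list
    released_per_zone: np.ndarray
    window_days: tuple = DEFAULT_WINDOW_DAYS

    @property
    def total_recruits(self) -> int:
        return int(self.counts.sum())

    @property
    def retained(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.zone_ids, columns=self.zone_ids)

    def to_csv(self, path, sidecar_path=None) -> None:
        self.to_frame().to_csv(path, index_label="release_zone")
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "window_days": list(self.window_days),
                        "total_recruits": self.total_recruits,
                        "retained": self.retained,
                        "released_per_zone": {
                            z: int(n) for z, n in zip(self.zone_ids, self.released_per_zone)
                        },
                    },
                    fh, indent=2,
                )


def recruit(
    traj: TrajectorySet,
    zones: ZoneSet,
    window_days: tuple = DEFAULT_WINDOW_DAYS,
) -> np.ndarray:
    """Per-particle recruitment zone index (-1 = never recruited).

    A particle recruits to the zone containing it at the first snapshot with
    age in [window_days[0], window_days[1]]; snapshots where the particle
    has already beached or exited do not count.
    """
    lo, hi = (window_days[0] * DAY_S, window_days[1] * DAY_S)
    if hi > traj.duration_s + 1e-6:
        raise ConfigurationError(
            f"recruitment window up to {window_days[1]} d exceeds the "
            f"{traj.duration_s / DAY_S:.0f}-d trajectory duration"
        )
    ages = traj.ages()
    in_window = (ages >= lo - 1e-6) & (ages <= hi + 1e-6) & (traj.status == ACTIVE)
    p_idx, s_idx = np.nonzero(in_window)
    if p_idx.size == 0:
        return np.full(traj.n_particles, -1, dtype=np.int64)
    zone_at = locate_zone_many(zones, traj.lon[p_idx, s_idx], traj.lat[p_idx, s_idx])

    out = np.full(traj.n_particles, -1, dtype=np.int64)
    hit = zone_at >= 0
    # nonzero() walks row-major, so within a particle snapshots come in
    # ascending age order; the first hit per particle wins.
    ph, zh = p_idx[hit], zone_at[hit]
    first = np.full(traj.n_particles, -1, dtype=np.int64)
    seen = np.zeros(traj.n_particles, dtype=bool)
    order = np.arange(ph.size - 1, -1, -1)  # reverse so earliest overwrites
    first[ph[order]] = order
    seen[ph] = True
    out[seen] = zh[first[seen]]
    return out


def connectivity_matrix(
    recruits: np.ndarray,
    release_zones: np.ndarray,
    zone_ids: list,
    window_days: tuple = DEFAULT_WINDOW_DAYS,
) -> ConnectivityMatrix:
    """Tally recruited particles into the release x recruitment count matrix."""
    recruits = np.asarray(recruits)
    release_zones = np.asarray(release_zones)
    if recruits.shape != release_zones.shape:
        raise DataError("recruit assignments and release zones must align by particle")
    nz = len(zone_ids)
    if recruits.size and (recruits.max() >= nz or release_zones.max() >= nz):
        raise DataError("zone index outside the declared zone set")
    ok = (recruits >= 0) & (release_zones >= 0)
    counts = np.zeros((nz, nz), dtype=np.int64)
    np.add.at(counts, (release_zones[ok], recruits[ok]), 1)
    released_per_zone = np.bincount(
        release_zones[release_zones >= 0], minlength=nz
    )
    return ConnectivityMatrix(
        counts=counts, zone_ids=list(zone_ids),
        released_per_zone=released_per_zone, window_days=tuple(window_days),
    )


def retention_fraction(m: ConnectivityMatrix, total_released: int) -> float:
    """Share (%) of released larvae recruited anywhere around the islands.

    The denominator is the total release; with zero flow and all releases
    inside zones this is 100%.
    """
    if total_released <= 0:
        raise ValueError("total_released must be positive")
    return round_pct(100.0 * m.total_recruits / total_released)


def source_contribution(m: ConnectivityMatrix) -> pd.Series:
    """Per release zone: percentage of all recruits it contributed (row sums)."""
    total = m.total_recruits
    if total == 0:
        raise ValueError("no recruits: source contributions are undefined")
    pct = [round_pct(100.0 * s / total) for s in m.counts.sum(axis=1)]
    return pd.Series(pct, index=m.zone_ids, name="source_pct")


def sink_proportion(m: ConnectivityMatrix) -> pd.Series:
    """Per recruitment zone: percentage of all recruits it received (column sums)."""
    total = m.total_recruits
    if total == 0:
        raise ValueError("no recruits: sink proportions are undefined")
    pct = [round_pct(100.0 * s / total) for s in m.counts.sum(axis=0)]
    return pd.Series(pct, index=m.zone_ids, name="sink_pct")


@dataclass
class DensityMap:
    """2-D histogram of drifting-particle positions."""

    counts: np.ndarray  # (n_lat_bins, n_lon_bins)
    lon_edges: np.ndarray
    lat_edges: np.ndarray

    def to_netcdf(self, path) -> None:
        import xarray as xr

        ds = xr.Dataset(
            {"density": (("lat_bin", "lon_bin"), self.counts)},
            coords={
                "lon_edge": ("lon_edge", self.lon_edges),
                "lat_edge": ("lat_edge", self.lat_edges),
            },
        )
        ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")


def density_map(
    traj: TrajectorySet,
    lon_edges: np.ndarray,
    lat_edges: np.ndarray,
    window_days: tuple | None = None,
) -> DensityMap:
    """Histogram of (particle, snapshot) positions of particles still
    drifting, optionally restricted to an age window in days."""
    lon_edges = np.asarray(lon_edges, dtype=float)
    lat_edges = np.asarray(lat_edges, dtype=float)
    if lon_edges.size < 2 or lat_edges.size < 2:
        raise ConfigurationError("density grid needs at least one bin per axis")
    ages = traj.ages()
    sel = (traj.status == ACTIVE) & (ages >= 0)
    if window_days is not None:
        sel &= (ages >= window_days[0] * DAY_S) & (ages <= window_days[1] * DAY_S)
    h, _, _ = np.histogram2d(
        traj.lat[sel].ravel(), traj.lon[sel].ravel(), bins=(lat_edges, lon_edges)
    )
    return DensityMap(counts=h, lon_edges=lon_edges, lat_edges=lat_edges)
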