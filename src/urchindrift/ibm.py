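"""Individual-based transport model for passive larvae.

Particles are released daily inside the zone ring, advected through the
gridded velocity field with classical fourth-order Runge-Kutta at a 120-s
step, and recorded on a global 6-hourly snapshot clock for 122 days of
larval life.  Larvae are passive: no swimming, no vertical migration, no
mortality.  A particle that is advected into an all-land cell beaches at
its last water position; one that leaves the grid exits; survivors finish
at their 122-day age.  All terminal states are absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import xarray as xr

from . import _kernels
from .errors import ConfigurationError, OutOfDomainError
from .hydro import VelocityField
from .zones import ZoneSet, locate_zone_many

DAY_S = 86_400.0

STATUS_NAMES = ("active", "beached", "exited", "finished")
ACTIVE, BEACHED, EXITED, FINISHED = range(4)


@dataclass
class ReleaseSchedule:
    """Daily particle releases over the spawning season.

    Defaults follow the production configuration: 6000 particles per day
    for 92 consecutive days (552,000 in total) released at 0-80 m depth
    over the full zone ring.
    """

    particles_per_day: int = 6000
    n_days: int = 92
    start_time: float = 0.0  # seconds on the field clock (June 1 in production)
    depth_range: tuple = (0.0, 80.0)
    seed: int = 0
    mode: str = "union"  # "union": uniform over the zone union; "per_zone": equal counts

    @property
    def total_particles(self) -> int:
        return self.particles_per_day * self.n_days


@dataclass
class ParticleRelease:
    """Initial state of every particle, in id order."""

    ids: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    release_time: np.ndarray  # seconds
    release_zone: np.ndarray  # int index into the ZoneSet, -1 if outside
    zone_ids: list

    def __len__(self) -> int:
        return self.ids.size


def _sample_in_polygon(poly, n, rng):
    """Uniform rejection sampling of n points inside a (multi)polygon."""
    minx, miny, maxx, maxy = poly.bounds
    xs = np.empty(n)
    ys = np.empty(n)
    got = 0
    while got < n:
        m = max(2 * (n - got), 64)
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(poly, cx, cy)
        k = min(int(keep.sum()), n - got)
        xs[got:got + k] = cx[keep][:k]
        ys[got:got + k] = cy[keep][:k]
        got += k
    return xs, ys


def build_release(schedule: ReleaseSchedule, zones: ZoneSet) -> ParticleRelease:
    """Place ``particles_per_day x n_days`` particles uniformly at random in
    the zone ring (or equal counts per zone), tag each with its release zone,
    and stamp daily release times.  Deterministic given the schedule seed."""
    union = zones.union()
    if union.area <= 0:
        raise ConfigurationError("zone union has zero area; nothing to seed")
    rng = np.random.default_rng(schedule.seed)
    n_total = schedule.total_particles
    lon = np.empty(n_total)
    lat = np.empty(n_total)

    pos = 0
    for _day in range(schedule.n_days):
        nd = schedule.particles_per_day
        if schedule.mode == "per_zone":
            base, extra = divmod(nd, len(zones.zones))
            for i, z in enumerate(zones.zones):
                ni = base + (1 if i < extra else 0)
                xs, ys = _sample_in_polygon(z.polygon, ni, rng)
                lon[pos:pos + ni] = xs
                lat[pos:pos + ni] = ys
                pos += ni
        elif schedule.mode == "union":
            xs, ys = _sample_in_polygon(union, nd, rng)
            lon[pos:pos + nd] = xs
            lat[pos:pos + nd] = ys
            pos += nd
        else:
            raise ConfigurationError(f"unknown release mode {schedule.mode!r}")

    z0, z1 = schedule.depth_range
    depth = rng.uniform(z0, z1, n_total)
    day_index = np.repeat(np.arange(schedule.n_days), schedule.particles_per_day)
    release_time = schedule.start_time + day_index * DAY_S
    release_zone = locate_zone_many(zones, lon, lat)
    return ParticleRelease(
        ids=np.arange(n_total),
        lon=lon, lat=lat, depth=depth,
        release_time=release_time.astype(np.float64),
        release_zone=release_zone,
        zone_ids=zones.ids,
    )


def rk4_step(field: VelocityField, position, t: float, dt: float):
    """One RK4 step of the larval motion equations dx/dt = u, dy/dt = v,
    dz/dt = w from ``position`` = (lon, lat, depth) at time ``t``.

    Horizontal velocities are converted from m/s to deg/s with Earth radius
    6371 km and cos(latitude); depth (positive down) advances as -w dt.
    Raises :class:`OutOfDomainError` carrying the last valid position when
    any stage evaluation leaves the grid.
    """
    x, y, z = (float(position[0]), float(position[1]), float(position[2]))
    xn, yn, zn, code = _kernels._rk4(
        *field._kernel_args(), x, y, z, float(t), float(dt)
    )
    if code == _kernels.OUT_OF_DOMAIN:
        raise OutOfDomainError(
            f"RK4 stage left the grid from (lon={x}, lat={y}, depth={z}, t={t})",
            last_position=(x, y, z),
        )
    return xn, yn, zn


@dataclass
class TrajectorySet:
    """Positions and statuses of all particles on the global snapshot grid.

    Arrays are (n_particles, n_snapshots); ``snapshot_times`` is seconds on
    the field clock.  Snapshots before a particle's release repeat its
    release position; snapshots after a terminal transition repeat its
    frozen state.
    """

    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    status: np.ndarray  # int8 codes, see STATUS_NAMES
    snapshot_times: np.ndarray
    release_time: np.ndarray
    release_zone: np.ndarray
    zone_ids: list
    dt: float
    duration_s: float
    epoch: str = "2000-01-01"

    @property
    def n_particles(self) -> int:
        return self.lon.shape[0]

    @property
    def n_snapshots(self) -> int:
        return self.snapshot_times.size

    def ages(self) -> np.ndarray:
        """Per-(particle, snapshot) age in seconds (negative before release)."""
        return self.snapshot_times[None, :] - self.release_time[:, None]

    def status_counts(self, snapshot: int = -1) -> dict:
        col = self.status[:, snapshot]
        return {name: int((col == code).sum()) for code, name in enumerate(STATUS_NAMES)}

    def to_netcdf(self, path) -> None:
        ds = xr.Dataset(
            {
                "lon": (("particle", "snapshot"), self.lon),
                "lat": (("particle", "snapshot"), self.lat),
                "depth": (("particle", "snapshot"), self.depth),
                "status": (("particle", "snapshot"), self.status.astype(np.int8),
                           {"flag_values": "0 1 2 3",
                            "flag_meanings": " ".join(STATUS_NAMES)}),
                "release_time": (("particle",), self.release_time),
                "release_zone": (("particle",), self.release_zone.astype(np.int32),
                                 {"zone_ids": " ".join(self.zone_ids)}),
            },
            coords={
                "snapshot_time": ("snapshot", self.snapshot_times,
                                  {"units": f"seconds since {self.epoch}"}),
            },
            attrs={"dt": self.dt, "duration_s": self.duration_s, "epoch": self.epoch},
        )
        ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")

    @classmethod
    def from_netcdf(cls, path) -> "TrajectorySet":
        with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
            ds = ds.load()
        return cls(
            lon=ds["lon"].values, lat=ds["lat"].values, depth=ds["depth"].values,
            status=ds["status"].values.astype(np.int8),
            snapshot_times=ds["snapshot_time"].values.astype(np.float64),
            release_time=ds["release_time"].values.astype(np.float64),
            release_zone=ds["release_zone"].values.astype(np.int64),
            zone_ids=str(ds["release_zone"].attrs["zone_ids"]).split(),
            dt=float(ds.attrs["dt"]), duration_s=float(ds.attrs["duration_s"]),
            epoch=str(ds.attrs.get("epoch", "2000-01-01")),
        )


def advect(
    release: ParticleRelease,
    field: VelocityField,
    dt: float = 120.0,
    duration_days: float = 122.0,
    output_every_hours: float = 6.0,
) -> TrajectorySet:
    """Integrate every particle for ``duration_days`` (or until a terminal
    status) and record 6-hourly snapshots on a global clock starting at the
    first release."""
    duration_s = duration_days * DAY_S
    out_s = output_every_hours * 3600.0
    t0 = float(release.release_time.min())
    t_end = float(release.release_time.max()) + duration_s
    if field.time[0] > t0 + 1e-6 or field.time[-1] < t_end - 1e-6:
        raise ConfigurationError(
            f"field time span [{field.time[0]}, {field.time[-1]}] does not cover "
            f"the run [{t0}, {t_end}]"
        )
    n_snap = int(round((t_end - t0) / out_s)) + 1
    snap_times = t0 + out_s * np.arange(n_snap)

    n = len(release)
    out_x = np.empty((n, n_snap))
    out_y = np.empty((n, n_snap))
    out_z = np.empty((n, n_snap))
    out_status = np.empty((n, n_snap), dtype=np.int8)
    _kernels._advect_kernel(
        *field._kernel_args(),
        np.ascontiguousarray(release.lon), np.ascontiguousarray(release.lat),
        np.ascontiguousarray(release.depth), np.ascontiguousarray(release.release_time),
        float(dt), float(duration_s), snap_times,
        out_x, out_y, out_z, out_status,
    )
    return TrajectorySet(
        lon=out_x, lat=out_y, depth=out_z, status=out_status,
        snapshot_times=snap_times,
        release_time=release.release_time.copy(),
        release_zone=release.release_zone.copy(),
        zone_ids=list(release.zone_ids),
        dt=dt, duration_s=duration_s, epoch=field.epoch,
    )
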