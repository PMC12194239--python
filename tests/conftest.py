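"""Shared fixtures: small synthetic fields, zone sets and trajectory builders.

Everything is generated programmatically at test time; no fixture files.
"""

import numpy as np
import pytest

from urchindrift.hydro import VelocityField
from urchindrift.ibm import DAY_S, TrajectorySet
from urchindrift.zones import synthetic_zoneset


def make_field(
    nx=5, ny=5, nz=3, nt=2,
    lon0=-79.0, lat0=-34.0, dlon=0.25, dlat=0.25,
    depths=(0.0, 50.0, 100.0),
    t_span=130 * DAY_S,
    u=0.0, v=0.0, w=None, mask=None, seed=None,
):
    """A small velocity field; u/v/w may be scalars or (nt,nz,ny,nx) arrays."""
    lon = lon0 + dlon * np.arange(nx)
    lat = lat0 + dlat * np.arange(ny)
    depth = np.asarray(depths[:nz], dtype=float)
    time = np.linspace(0.0, t_span, nt)
    shape = (nt, nz, ny, nx)
    if seed is not None:
        rng = np.random.default_rng(seed)
        uu = rng.normal(0.0, 0.1, shape)
        vv = rng.normal(0.0, 0.1, shape)
    else:
        uu = np.broadcast_to(np.asarray(u, dtype=float), shape).copy()
        vv = np.broadcast_to(np.asarray(v, dtype=float), shape).copy()
    ww = None if w is None else np.broadcast_to(np.asarray(w, dtype=float), shape).copy()
    return VelocityField(lon=lon, lat=lat, depth=depth, time=time,
                         u=uu, v=vv, w=ww, mask=mask)


def make_trajectory(points, snapshot_times, release_time=0.0, status=None,
                    zone_ids=None, duration_s=122 * DAY_S):
    """Hand-built single- or multi-particle TrajectorySet.

    ``points``: array (n_particles, n_snapshots, 3) of lon/lat/depth.
    """
    pts = np.asarray(points, dtype=float)
    n, ns, _ = pts.shape
    snapshot_times = np.asarray(snapshot_times, dtype=float)
    rel = np.broadcast_to(np.asarray(release_time, dtype=float), (n,)).copy()
    if status is None:
        status = np.zeros((n, ns), dtype=np.int8)
    return TrajectorySet(
        lon=pts[:, :, 0], lat=pts[:, :, 1], depth=pts[:, :, 2],
        status=np.asarray(status, dtype=np.int8),
        snapshot_times=snapshot_times,
        release_time=rel,
        release_zone=np.zeros(n, dtype=np.int64),
        zone_ids=list(zone_ids) if zone_ids else ["RC_A", "RC_B", "RC_C",
                                                  "RC_D", "RC_E", "RC_F"],
        dt=120.0, duration_s=duration_s,
    )


@pytest.fixture(scope="session")
def ring_zones():
    return synthetic_zoneset()
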