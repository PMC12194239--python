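"""Numba-compiled numerical core: field interpolation, RK4, particle stepping.

Everything here operates on bare float64 arrays so that the same compiled
code backs both the public single-point API (`hydro.interpolate_velocity`,
`ibm.rk4_step`) and the full particle loop (`ibm.advect`).  Keeping one
kernel avoids any drift between the step used in tests and the step used in
production runs.

Conventions fixed here and relied on everywhere else:
  * horizontal positions in degrees, depth in metres positive down,
    time in seconds;
  * velocities in m s^-1, w positive up (so depth evolves as -w);
  * status codes 0=active, 1=beached, 2=exited, 3=finished.

Grid axes known to be uniform are located by direct index arithmetic
(``ax_params`` packs origin and inverse spacing per axis, inverse spacing 0
meaning "not uniform, binary-search instead"); this dominates the cost of a
full 122-day integration, so the fast path matters.
"""

import numpy as np
from numba import njit

R_EARTH_M = 6_371_000.0
#: metres per degree of latitude (and of longitude at the equator)
M_PER_DEG = R_EARTH_M * np.pi / 180.0

# cell-state / interpolation return codes
OK = 0
OUT_OF_DOMAIN = 1
ALL_LAND = 2

# particle status codes
ACTIVE = 0
BEACHED = 1
EXITED = 2
FINISHED = 3


def axis_params(grid: np.ndarray) -> tuple:
    """(origin, inverse spacing) of a 1-D axis; inverse spacing 0 when the
    axis is not uniformly spaced (within 1e-9 relative)."""
    if grid.size < 2:
        return float(grid[0]), 0.0
    d = np.diff(grid)
    if np.allclose(d, d[0], rtol=1e-9, atol=1e-12 * max(1.0, abs(float(grid[-1])))):
        return float(grid[0]), 1.0 / float(d[0])
    return float(grid[0]), 0.0


@njit(cache=True, inline="always", fastmath=True)
def _locate(grid, x, x0, inv_dx):
    """Bracket ``x`` in a strictly increasing 1-D grid.

    Returns (i0, frac) with grid[i0] <= x <= grid[i0+1] (frac in [0,1]),
    or (-1, 0.0) when x lies outside [grid[0], grid[-1]].  A length-1 grid
    accepts only its single value (frac 0), tolerantly.
    """
    n = grid.shape[0]
    if n == 1:
        if abs(x - grid[0]) < 1e-9 * (1.0 + abs(grid[0])):
            return 0, 0.0
        return -1, 0.0
    if x < grid[0] or x > grid[n - 1]:
        return -1, 0.0
    if inv_dx > 0.0:
        f = (x - x0) * inv_dx
        i = int(f)
        if i >= n - 1:
            i = n - 2
        return i, f - i
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if grid[mid] <= x:
            lo = mid
        else:
            hi = mid
    return lo, (x - grid[lo]) / (grid[lo + 1] - grid[lo])


@njit(cache=True, inline="always", fastmath=True)
def _interp(lon_g, lat_g, dep_g, tim_g, ax, u4, v4, w4, has_w, z_const, t_const,
            wet, x, y, z, t):
    """Tri-linear space / linear time interpolation with land masking.

    Land nodes contribute zero velocity and their weight is renormalised
    over the water nodes of the enclosing cell; a cell whose eight spatial
    corners are all land yields (0,0,0, ALL_LAND).

    ``z_const`` / ``t_const`` assert that the field (and, for depth, the
    mask) is identical along that axis, so a single level can stand for the
    bracketing pair; bounds are still enforced.
    """
    ix, fx = _locate(lon_g, x, ax[0], ax[1])
    iy, fy = _locate(lat_g, y, ax[2], ax[3])
    iz, fz = _locate(dep_g, z, ax[4], ax[5])
    it, ft = _locate(tim_g, t, ax[6], ax[7])
    if ix < 0 or iy < 0 or iz < 0 or it < 0:
        return 0.0, 0.0, 0.0, OUT_OF_DOMAIN
    if z_const:
        iz = 0
        fz = 0.0
    if t_const:
        it = 0
        ft = 0.0

    ix1 = min(ix + 1, lon_g.shape[0] - 1)
    iy1 = min(iy + 1, lat_g.shape[0] - 1)
    iz1 = min(iz + 1, dep_g.shape[0] - 1)
    it1 = min(it + 1, tim_g.shape[0] - 1)

    usum = 0.0
    vsum = 0.0
    wsum = 0.0
    wtot = 0.0
    for cz in range(2):
        kz = iz if cz == 0 else iz1
        wz = (1.0 - fz) if cz == 0 else fz
        if wz == 0.0:
            continue
        for cy in range(2):
            ky = iy if cy == 0 else iy1
            wy = (1.0 - fy) if cy == 0 else fy
            if wy == 0.0:
                continue
            for cx in range(2):
                kx = ix if cx == 0 else ix1
                wx = (1.0 - fx) if cx == 0 else fx
                if wx == 0.0:
                    continue
                if not wet[kz, ky, kx]:
                    continue
                wgt = wz * wy * wx
                if ft == 0.0:
                    usum += wgt * u4[it, kz, ky, kx]
                    vsum += wgt * v4[it, kz, ky, kx]
                    if has_w:
                        wsum += wgt * w4[it, kz, ky, kx]
                else:
                    usum += wgt * ((1.0 - ft) * u4[it, kz, ky, kx]
                                   + ft * u4[it1, kz, ky, kx])
                    vsum += wgt * ((1.0 - ft) * v4[it, kz, ky, kx]
                                   + ft * v4[it1, kz, ky, kx])
                    if has_w:
                        wsum += wgt * ((1.0 - ft) * w4[it, kz, ky, kx]
                                       + ft * w4[it1, kz, ky, kx])
                wtot += wgt
    if wtot <= 0.0:
        return 0.0, 0.0, 0.0, ALL_LAND
    return usum / wtot, vsum / wtot, wsum / wtot, OK


@njit(cache=True)
def _interp_many(lon_g, lat_g, dep_g, tim_g, ax, u4, v4, w4, has_w,
                 z_const, t_const, wet, xs, ys, zs, ts):
    n = xs.shape[0]
    out = np.empty((n, 3))
    codes = np.empty(n, dtype=np.int8)
    for i in range(n):
        u, v, w, c = _interp(lon_g, lat_g, dep_g, tim_g, ax, u4, v4, w4, has_w,
                             z_const, t_const, wet, xs[i], ys[i], zs[i], ts[i])
        out[i, 0] = u
        out[i, 1] = v
        out[i, 2] = w
        codes[i] = c
    return out, codes


@njit(cache=True, inline="always", fastmath=True)
def _deriv(u, v, w, lat):
    """(dlon/dt, dlat/dt, ddepth/dt) in (deg/s, deg/s, m/s) from m/s velocities."""
    coslat = np.cos(lat * np.pi / 180.0)
    if coslat < 1e-6:
        coslat = 1e-6
    return u / (M_PER_DEG * coslat), v / M_PER_DEG, -w


@njit(cache=True, inline="always", fastmath=True)
def _rk4(lon_g, lat_g, dep_g, tim_g, ax, u4, v4, w4, has_w, z_const, t_const,
         wet, x, y, z, t, dt):
    """One classical RK4 step of dx/dt=u, dy/dt=v, dz/dt=w.

    Returns (xn, yn, zn, code); on a non-zero code the input position is
    returned unchanged (the caller decides the particle's fate).
    """
    u, v, w, c = _interp(lon_g, lat_g, dep_g, tim_g, ax, u4, v4, w4, has_w,
                         z_const, t_const, wet, x, y, z, t)
    if c != OK:
        return x, y, z, c
    k1x, k1y, k1z = _deriv(u, v, w, y)

    u, v, w, c = _interp(lon_g, lat_g, dep_g, tim_g, ax, u4, v4, w4, has_w,
                         z_const, t_const, wet,
                         x + 0.5 * dt * k1x, y + 0.5 * dt * k1y, z + 0.5 * dt * k1z,
                         t + 0.5 * dt)
    if c != OK:
        return x, y, z, c
    k2x, k2y, k2z = _deriv(u, v, w, y + 0.5 * dt * k1y)

    u, v, w, c = _interp(lon_g, lat_g, dep_g, tim_g, ax, u4, v4, w4, has_w,
                         z_const, t_const, wet,
                         x + 0.5 * dt * k2x, y + 0.5 * dt * k2y, z + 0.5 * dt * k2z,
                         t + 0.5 * dt)
    if c != OK:
        return x, y, z, c
    k3x, k3y, k3z = _deriv(u, v, w, y + 0.5 * dt * k2y)

    u, v, w, c = _interp(lon_g, lat_g, dep_g, tim_g, ax, u4, v4, w4, has_w,
                         z_const, t_const, wet,
                         x + dt * k3x, y + dt * k3y, z + dt * k3z, t + dt)
    if c != OK:
        return x, y, z, c
    k4x, k4y, k4z = _deriv(u, v, w, y + dt * k3y)

    xn = x + dt / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
    yn = y + dt / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
    zn = z + dt / 6.0 * (k1z + 2.0 * k2z + 2.0 * k3z + k4z)
    return xn, yn, zn, OK


@njit(cache=True, inline="always", fastmath=True)
def _cell_state(lon_g, lat_g, dep_g, ax, wet, x, y, z):
    """Classify a position: OK (some water corner), OUT_OF_DOMAIN, or ALL_LAND."""
    ix, fx = _locate(lon_g, x, ax[0], ax[1])
    iy, fy = _locate(lat_g, y, ax[2], ax[3])
    iz, fz = _locate(dep_g, z, ax[4], ax[5])
    if ix < 0 or iy < 0 or iz < 0:
        return OUT_OF_DOMAIN
    ix1 = min(ix + 1, lon_g.shape[0] - 1)
    iy1 = min(iy + 1, lat_g.shape[0] - 1)
    iz1 = min(iz + 1, dep_g.shape[0] - 1)
    for kz in (iz, iz1):
        for ky in (iy, iy1):
            for kx in (ix, ix1):
                if wet[kz, ky, kx]:
                    return OK
    return ALL_LAND


@njit(cache=True, fastmath=True)
def _advect_kernel(lon_g, lat_g, dep_g, tim_g, ax, u4, v4, w4, has_w,
                   z_const, t_const, wet,
                   x0, y0, z0, rel_t, dt, duration_s, snap_times,
                   out_x, out_y, out_z, out_status):
    """Integrate every particle and record state on the global snapshot grid.

    A particle holds its release position (status ACTIVE) at snapshots before
    its release time; after a terminal transition its frozen state is copied
    into all remaining snapshots, so particle count is conserved at every
    snapshot by construction.
    """
    n = x0.shape[0]
    n_snap = snap_times.shape[0]
    for p in range(n):
        x = x0[p]
        y = y0[p]
        z = z0[p]
        t = rel_t[p]
        st = ACTIVE
        t_stop = rel_t[p] + duration_s
        for k in range(n_snap):
            ts = snap_times[k]
            while st == ACTIVE and t < t_stop - 1e-6 and t < ts - 1e-6:
                h = dt
                if t + dt > ts + 1e-6:
                    h = ts - t
                if t + h > t_stop + 1e-6:
                    h = t_stop - t
                xn, yn, zn, code = _rk4(lon_g, lat_g, dep_g, tim_g, ax,
                                        u4, v4, w4, has_w, z_const, t_const, wet,
                                        x, y, z, t, h)
                if code == OUT_OF_DOMAIN:
                    st = EXITED
                elif code == ALL_LAND:
                    st = BEACHED
                else:
                    landing = _cell_state(lon_g, lat_g, dep_g, ax, wet, xn, yn, zn)
                    if landing == OUT_OF_DOMAIN:
                        st = EXITED
                    elif landing == ALL_LAND:
                        st = BEACHED  # freeze at last water position
                    else:
                        x = xn
                        y = yn
                        z = zn
                        t += h
            if st == ACTIVE and t >= t_stop - 1e-6:
                st = FINISHED
            out_x[p, k] = x
            out_y[p, k] = y
            out_z[p, k] = z
            out_status[p, k] = st
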