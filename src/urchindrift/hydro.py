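"""Gridded ocean velocity fields: container, NetCDF I/O, interpolation, summaries.

The in-memory container (:class:`VelocityField`) mirrors the layout of
CMEMS-style reanalysis products: regular lon/lat/depth/time axes with u/v
(and optionally w) velocity components and a static land mask.  The module
owns the space-time interpolation contract consumed by the particle model:
tri-linear in (lon, lat, depth), linear in time, with land nodes excluded
by weight renormalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr

from . import _kernels
from .errors import EmptySelectionError, FormatError, OutOfDomainError, ValidationError

#: default mapping of roles to CMEMS-dialect variable names
DEFAULT_VAR_NAMES = {
    "lon": "longitude",
    "lat": "latitude",
    "depth": "depth",
    "time": "time",
    "u": "uo",
    "v": "vo",
    "w": "wo",
}


@dataclass
class VelocityField:
    """Velocity components on a regular lon x lat x depth x time grid.

    Axis order of ``u``/``v``/``w`` is (time, depth, lat, lon).  Depth is in
    metres, positive down, starting at the surface; ``w`` is positive up.
    ``mask`` is (depth, lat, lon), True over water; a missing mask means
    all-water.  ``time`` is seconds since ``epoch``.
    """

    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    time: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray | None = None
    mask: np.ndarray | None = None
    epoch: str = "2000-01-01"
    _w_filled: np.ndarray | None = dc_field(default=None, repr=False, compare=False)
    _kernel_cache: tuple | None = dc_field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=np.float64)
        self.lat = np.asarray(self.lat, dtype=np.float64)
        self.depth = np.asarray(self.depth, dtype=np.float64)
        self.time = np.asarray(self.time, dtype=np.float64)
        self.u = np.ascontiguousarray(self.u, dtype=np.float64)
        self.v = np.ascontiguousarray(self.v, dtype=np.float64)
        if self.w is not None:
            self.w = np.ascontiguousarray(self.w, dtype=np.float64)
        if self.mask is None:
            self.mask = np.ones(
                (self.depth.size, self.lat.size, self.lon.size), dtype=bool
            )
        else:
            self.mask = np.ascontiguousarray(self.mask, dtype=bool)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        for name in ("lon", "lat", "depth", "time"):
            coord = getattr(self, name)
            if coord.ndim != 1 or coord.size == 0:
                raise ValidationError(f"coordinate {name!r} must be 1-D and non-empty")
            if coord.size > 1 and not np.all(np.diff(coord) > 0):
                raise ValidationError(f"coordinate {name!r} must be strictly increasing")
        if self.depth[0] < 0:
            raise ValidationError("depth must be positive down, starting at >= 0 m")
        shape = (self.time.size, self.depth.size, self.lat.size, self.lon.size)
        for name in ("u", "v"):
            if getattr(self, name).shape != shape:
                raise ValidationError(
                    f"{name} has shape {getattr(self, name).shape}, expected {shape}"
                )
        if self.w is not None and self.w.shape != shape:
            raise ValidationError(f"w has shape {self.w.shape}, expected {shape}")
        if self.mask.shape != shape[1:]:
            raise ValidationError(
                f"mask has shape {self.mask.shape}, expected {shape[1:]}"
            )
        wet = self.mask[None, :, :, :]
        for name in ("u", "v", "w"):
            arr = getattr(self, name)
            if arr is not None and not np.all(np.isfinite(arr[np.broadcast_to(wet, shape)])):
                raise ValidationError(f"{name} contains non-finite values over water")

    # -- helpers ---------------------------------------------------------

    @property
    def w_or_zero(self) -> np.ndarray:
        """``w`` with an all-zero array standing in when absent."""
        if self.w is not None:
            return self.w
        if self._w_filled is None or self._w_filled.shape != self.u.shape:
            self._w_filled = np.zeros_like(self.u)
        return self._w_filled

    def time_as_datetime(self) -> np.ndarray:
        return np.datetime64(self.epoch) + self.time.astype("timedelta64[s]")

    def _kernel_args(self):
        if self._kernel_cache is None:
            ax = np.empty(8)
            for i, coord in enumerate((self.lon, self.lat, self.depth, self.time)):
                ax[2 * i], ax[2 * i + 1] = _kernels.axis_params(coord)
            has_w = self.w is not None
            # exactness shortcuts: a field (and mask) identical along depth or
            # time lets the kernel read a single level for the bracketing pair
            arrays = [self.u, self.v] + ([self.w] if has_w else [])
            z_const = all(
                np.array_equal(a[:, :1], a[:, k:k + 1])
                for a in arrays for k in range(1, self.depth.size)
            ) and all(
                np.array_equal(self.mask[:1], self.mask[k:k + 1])
                for k in range(1, self.depth.size)
            )
            t_const = all(
                np.array_equal(a[:1], a[k:k + 1])
                for a in arrays for k in range(1, self.time.size)
            )
            # u stands in for the unread w slot when w is absent
            self._kernel_cache = (
                self.lon, self.lat, self.depth, self.time, ax,
                self.u, self.v, self.w if has_w else self.u, has_w,
                z_const, t_const, self.mask,
            )
        return self._kernel_cache


# -- NetCDF I/O ----------------------------------------------------------


def write_velocity_netcdf(field: VelocityField, path) -> None:
    """Write a CF-style NetCDF (classic format) losslessly round-trippable by
    :func:`read_velocity_netcdf`.  Land cells are stored as NaN."""
    land4 = np.broadcast_to(~field.mask, field.u.shape)
    data_vars = {
        "uo": (("time", "depth", "latitude", "longitude"),
               np.where(land4, np.nan, field.u),
               {"units": "m s-1", "long_name": "eastward velocity"}),
        "vo": (("time", "depth", "latitude", "longitude"),
               np.where(land4, np.nan, field.v),
               {"units": "m s-1", "long_name": "northward velocity"}),
    }
    if field.w is not None:
        data_vars["wo"] = (
            ("time", "depth", "latitude", "longitude"),
            np.where(land4, np.nan, field.w),
            {"units": "m s-1", "long_name": "upward velocity", "positive": "up"},
        )
    ds = xr.Dataset(
        data_vars,
        coords={
            "longitude": ("longitude", field.lon, {"units": "degrees_east"}),
            "latitude": ("latitude", field.lat, {"units": "degrees_north"}),
            "depth": ("depth", field.depth, {"units": "m", "positive": "down"}),
            "time": ("time", field.time, {"units": f"seconds since {field.epoch}"}),
        },
    )
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")


def read_velocity_netcdf(path, var_names: dict | None = None) -> VelocityField:
    """Read and validate a velocity field from NetCDF.

    ``var_names`` maps roles (lon/lat/depth/time/u/v/w) to variable names in
    the file; unspecified roles use the CMEMS-dialect defaults.  Fill values
    become land in the mask; a depth axis stored negative-up is flipped to
    positive-down; a ``w`` stored positive-down is negated to positive-up.
    """
    names = dict(DEFAULT_VAR_NAMES)
    if var_names:
        names.update(var_names)
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        ds = ds.load()

    def _require(role):
        name = names[role]
        if name not in ds.variables:
            raise FormatError(f"missing variable {name!r} for role {role!r}")
        return ds[name]

    coords = {}
    for role in ("lon", "lat", "depth", "time"):
        coords[role] = np.asarray(_require(role).values, dtype=np.float64)

    depth = coords["depth"]
    if depth.size > 1 and np.all(depth <= 0):  # elevation convention
        depth = -depth[::-1]
        flip_depth = True
    else:
        flip_depth = False

    time_var = ds[names["time"]]
    epoch = "2000-01-01"
    units = str(time_var.attrs.get("units", ""))
    if "since" in units:
        epoch = units.split("since", 1)[1].strip()

    def _velocity(role, required):
        name = names[role]
        if name not in ds.variables:
            if required:
                raise FormatError(f"missing variable {name!r} for role {role!r}")
            return None
        arr = np.asarray(ds[name].values, dtype=np.float64)
        fill = ds[name].attrs.get("_FillValue")
        if fill is not None:
            arr = np.where(arr == fill, np.nan, arr)
        if arr.ndim == 3:  # depth-less file: add a singleton depth axis
            arr = arr[:, None, :, :]
        if flip_depth:
            arr = arr[:, ::-1, :, :]
        return arr

    u = _velocity("u", required=True)
    v = _velocity("v", required=True)
    w = _velocity("w", required=False)
    if w is not None and str(ds[names["w"]].attrs.get("positive", "up")).lower() == "down":
        w = -w

    mask = np.isfinite(u).all(axis=0) & np.isfinite(v).all(axis=0)
    if w is not None:
        mask &= np.isfinite(w).all(axis=0)
    u = np.nan_to_num(u, nan=0.0)
    v = np.nan_to_num(v, nan=0.0)
    if w is not None:
        w = np.nan_to_num(w, nan=0.0)

    return VelocityField(
        lon=coords["lon"], lat=coords["lat"], depth=depth, time=coords["time"],
        u=u, v=v, w=w, mask=mask, epoch=epoch,
    )


# -- interpolation -------------------------------------------------------


def interpolate_velocity(field: VelocityField, lon, lat, depth, t):
    """Interpolate (u, v, w) in m s^-1 at one or many query points.

    Tri-linear in space, linear in time; land nodes contribute zero with
    weights renormalised over water nodes; (0, 0, 0) inside an all-land
    cell.  Raises :class:`OutOfDomainError` for any point outside the grid.
    """
    scalar = np.isscalar(lon) or (np.ndim(lon) == 0)
    xs = np.atleast_1d(np.asarray(lon, dtype=np.float64))
    ys = np.atleast_1d(np.asarray(lat, dtype=np.float64))
    zs = np.atleast_1d(np.asarray(depth, dtype=np.float64))
    ts = np.atleast_1d(np.asarray(t, dtype=np.float64))
    xs, ys, zs, ts = np.broadcast_arrays(xs, ys, zs, ts)
    out, codes = _kernels._interp_many(
        *field._kernel_args(),
        np.ascontiguousarray(xs), np.ascontiguousarray(ys),
        np.ascontiguousarray(zs), np.ascontiguousarray(ts),
    )
    if np.any(codes == _kernels.OUT_OF_DOMAIN):
        i = int(np.argmax(codes == _kernels.OUT_OF_DOMAIN))
        raise OutOfDomainError(
            f"query point (lon={xs[i]}, lat={ys[i]}, depth={zs[i]}, t={ts[i]}) "
            "is outside the grid",
            last_position=(xs[i], ys[i], zs[i]),
        )
    if scalar:
        return float(out[0, 0]), float(out[0, 1]), float(out[0, 2])
    return out[:, 0], out[:, 1], out[:, 2]


# -- summaries -----------------------------------------------------------


def seasonal_mean_velocity(field: VelocityField, months, max_depth: float = 100.0):
    """Mean (u, v) maps over the requested calendar months, averaged over all
    depth levels <= ``max_depth``, water cells only (NaN over land columns).

    ``months`` is a collection of month numbers (1-12) or English names.
    """
    month_numbers = set()
    for m in months:
        if isinstance(m, str):
            month_numbers.add(_MONTH_NUMBERS[m.strip().lower()[:3]])
        else:
            month_numbers.add(int(m))
    dt = field.time_as_datetime()
    file_months = dt.astype("datetime64[M]").astype(int) % 12 + 1
    t_sel = np.isin(file_months, sorted(month_numbers))
    if not t_sel.any():
        raise EmptySelectionError(f"no time steps fall in months {sorted(month_numbers)}")
    z_sel = field.depth <= max_depth
    if not z_sel.any():
        raise EmptySelectionError(f"no depth levels at or above {max_depth} m")

    wet = field.mask[z_sel]  # (nz_sel, ny, nx)
    nwater = wet.sum(axis=0).astype(float)  # water levels per column
    nt = int(t_sel.sum())

    def _mean(arr):
        sub = arr[t_sel][:, z_sel]  # (nt, nz_sel, ny, nx)
        total = np.where(wet[None], sub, 0.0).sum(axis=(0, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = total / (nt * nwater)
        out[nwater == 0] = np.nan
        return out

    return _mean(field.u), _mean(field.v)


_MONTH_NUMBERS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}
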