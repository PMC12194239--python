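"""Config-driven orchestration of the four stages.

A :class:`RunConfig` (YAML-loadable) names the velocity-field source, zone
geometry, release schedule, IBM numerics, recruitment window and abundance
inputs.  One global seed is fanned out to per-stage child seeds by a fixed
`numpy.random.SeedSequence` derivation, so any stage can be rerun
independently yet bit-identically.  Each stage writes its artifacts plus a
JSON manifest (config hash, seeds, status tallies) into the output
directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import connectivity as conn
from . import glm, hydro, ibm, synthetic, zones as zones_mod
from .errors import ConfigurationError

log = logging.getLogger("urchindrift")

STAGE_NAMES = ("field", "release", "ibm", "abundance")


@dataclass
class RunConfig:
    """Everything needed to rerun the pipeline bit-identically."""

    out_dir: str = "run_output"
    seed: int = 0
    # field stage: either a preset scenario name or a NetCDF path
    field_scenario: str | None = "retention"
    field_path: str | None = None
    # zones: synthetic ring parameters or a GeoJSON path
    zones_geojson: str | None = None
    island_center: tuple = zones_mod.DEFAULT_ISLAND_CENTER
    island_radius_km: float = 8.0
    ring_width_km: float = 8.0
    # release schedule
    particles_per_day: int = 100
    n_release_days: int = 10
    release_depth_range: tuple = (0.0, 80.0)
    release_mode: str = "union"
    # IBM numerics
    dt_s: float = 120.0
    duration_days: float = 122.0
    output_every_hours: float = 6.0
    # recruitment
    window_days: tuple = (110.0, 120.0)
    # abundance stage: a trap CSV or a synthetic scenario
    trap_csv: str | None = None
    catch_n_records: int = 8000
    glm_family: str = "zinb"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.field_scenario is None and self.field_path is None:
            raise ConfigurationError("either field_scenario or field_path is required")
        if (
            self.field_scenario is not None
            and self.field_path is None
            and self.field_scenario not in synthetic.FLOW_PRESETS
        ):
            raise ConfigurationError(
                f"unknown flow scenario {self.field_scenario!r}; "
                f"presets: {sorted(synthetic.FLOW_PRESETS)}"
            )
        if self.window_days[1] > self.duration_days:
            raise ConfigurationError(
                f"recruitment window up to day {self.window_days[1]} needs a run of "
                f"at least that many days (duration_days={self.duration_days})"
            )
        if self.glm_family not in glm.FAMILIES:
            raise ConfigurationError(f"glm_family must be one of {glm.FAMILIES}")

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def stage_seeds(self) -> dict:
        children = np.random.SeedSequence(self.seed).spawn(len(STAGE_NAMES))
        return {
            name: int(c.generate_state(1, dtype=np.uint32)[0]) % (2**31)
            for name, c in zip(STAGE_NAMES, children)
        }


def _write_manifest(cfg: RunConfig, stage: str, extra: dict) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seeds": cfg.stage_seeds(),
        **extra,
    }
    path = out / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


def load_zones(cfg: RunConfig) -> zones_mod.ZoneSet:
    if cfg.zones_geojson:
        return zones_mod.read_zoneset_geojson(cfg.zones_geojson)
    return zones_mod.synthetic_zoneset(
        island_center=tuple(cfg.island_center),
        island_radius_km=cfg.island_radius_km,
        ring_width_km=cfg.ring_width_km,
    )


def cmd_make_field(cfg: RunConfig) -> Path:
    """Generate (or validate) the velocity field and write it as NetCDF."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.field_path:
        field = hydro.read_velocity_netcdf(cfg.field_path)
        log.info("field: validated %s", cfg.field_path)
        dest = Path(cfg.field_path)
    else:
        scenario = synthetic.FLOW_PRESETS[cfg.field_scenario]()
        scenario.seed = cfg.stage_seeds()["field"]
        field = synthetic.make_flow_field(scenario, synthetic.retention_grid())
        dest = out / "velocity_field.nc"
        hydro.write_velocity_netcdf(field, dest)
        log.info("field: wrote %s (%s)", dest, cfg.field_scenario)
    _write_manifest(cfg, "field", {
        "path": str(dest),
        "grid": {
            "lon": len(field.lon), "lat": len(field.lat),
            "depth": len(field.depth), "time": len(field.time),
        },
    })
    return dest


def cmd_run_ibm(cfg: RunConfig, field_path=None) -> Path:
    """Release particles and advect them; write trajectories + manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    field_path = field_path or (
        cfg.field_path if cfg.field_path else out / "velocity_field.nc"
    )
    field = hydro.read_velocity_netcdf(field_path)
    zones = load_zones(cfg)
    schedule = ibm.ReleaseSchedule(
        particles_per_day=cfg.particles_per_day,
        n_days=cfg.n_release_days,
        start_time=float(field.time[0]),
        depth_range=tuple(cfg.release_depth_range),
        seed=cfg.stage_seeds()["release"],
        mode=cfg.release_mode,
    )
    release = ibm.build_release(schedule, zones)
    traj = ibm.advect(
        release, field,
        dt=cfg.dt_s, duration_days=cfg.duration_days,
        output_every_hours=cfg.output_every_hours,
    )
    # status tallies every simulated 10 days
    for k in range(0, traj.n_snapshots, int(10 * 86400 / (cfg.output_every_hours * 3600))):
        log.info("ibm: day %5.1f %s", traj.snapshot_times[k] / 86400.0,
                 traj.status_counts(k))
    dest = out / "trajectories.nc"
    traj.to_netcdf(dest)
    counts = traj.status_counts(-1)
    _write_manifest(cfg, "ibm", {
        "path": str(dest),
        "released": len(release),
        "final_status_counts": counts,
    })
    return dest


def cmd_connectivity(cfg: RunConfig, traj_path=None) -> dict:
    """Recruit particles, tally the connectivity matrix, write CSV + summary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    traj = ibm.TrajectorySet.from_netcdf(traj_path or out / "trajectories.nc")
    zones = load_zones(cfg)
    recruits = conn.recruit(traj, zones, tuple(cfg.window_days))
    m = conn.connectivity_matrix(
        recruits, traj.release_zone, zones.ids, tuple(cfg.window_days)
    )
    m.to_csv(out / "connectivity_matrix.csv", out / "connectivity_meta.json")

    lon_edges = np.linspace(traj.lon.min(), traj.lon.max() + 1e-9, 51)
    lat_edges = np.linspace(traj.lat.min(), traj.lat.max() + 1e-9, 51)
    dm = conn.density_map(traj, lon_edges, lat_edges, tuple(cfg.window_days))
    dm.to_netcdf(out / "density_map.nc")

    summary = {"total_recruits": m.total_recruits, "released": traj.n_particles}
    if m.total_recruits > 0:
        src = conn.source_contribution(m)
        snk = conn.sink_proportion(m)
        summary.update({
            "retention_fraction_pct": conn.retention_fraction(m, traj.n_particles),
            "top_source": {"zone": src.idxmax(), "pct": float(src.max())},
            "top_sink": {"zone": snk.idxmax(), "pct": float(snk.max())},
            "source_pct": src.to_dict(),
            "sink_pct": snk.to_dict(),
        })
    else:
        log.warning("connectivity: no particles recruited in the window")
    with open(out / "connectivity_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    _write_manifest(cfg, "connectivity", summary)
    return summary


def cmd_fit_abundance(cfg: RunConfig) -> Path:
    """Fit the m1-m5 / M1-M5 ladder and write model-selection + coefficients CSVs."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.trap_csv:
        table = glm.TrapHaulTable.from_csv(cfg.trap_csv)
    else:
        scenario = synthetic.default_catch_scenario(
            n_records=cfg.catch_n_records, seed=cfg.stage_seeds()["abundance"]
        )
        table = synthetic.make_trap_table(scenario)
        table.to_csv(out / "trap_hauls.csv")
    ranking = glm.model_selection(table, family=cfg.glm_family)
    dest = out / "model_selection.csv"
    ranking.drop(columns=[]).to_csv(dest, index=False)
    best_name = ranking.iloc[0]["model"]
    fits = ranking.attrs.get("fits", {})
    if best_name in fits:
        best = fits[best_name]
        coef = best.coefficients.to_frame("estimate")
        if best.phi is not None:
            coef.loc["phi"] = best.phi
        if best.pi is not None:
            coef.loc["pi"] = best.pi
        coef.to_csv(out / "best_model_coefficients.csv", index_label="term")
    _write_manifest(cfg, "abundance", {
        "n_records": len(table),
        "best_model": str(best_name),
        "best_aic": float(ranking.iloc[0]["aic"]),
    })
    return dest


def run_all(cfg: RunConfig) -> dict:
    """Run all four stages in order; returns the connectivity summary."""
    cmd_make_field(cfg)
    cmd_run_ibm(cfg)
    summary = cmd_connectivity(cfg)
    cmd_fit_abundance(cfg)
    return summary
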