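"""Lagrangian larval transport: advection–diffusion stepping, land and
boundary handling, bathymetry clamping, mortality, and settlement.

Each larva is advanced on a 2-h timestep.  Per step the displacement is

    dx_east  = u·dt + N(0, sqrt(2·D·dt))
    dx_north = v·dt + N(0, sqrt(2·D·dt))

with (u, v) bilinearly interpolated from the daily current snapshot at
the larva's layer, and D a horizontal diffusion constant (default
0.2 m²/s).  Meters convert to degrees on a sphere of radius
R = 6,378,137 m (the same radius the connectivity distances use).
A step whose destination cell is land is rejected (the larva waits); a
step beyond the grid extent terminates the trajectory (``left_domain``).
After each move the larva's layer is re-clamped to the bathymetry at
its new position.  Mortality is an independent per-step Bernoulli draw
matching the species half-life (half of larvae survive to half the
maximum PLD).  At its assigned PLD a larva settles to the nearest
habitat-suitable site within the settlement radius (default 1 km) or is
removed (``expired``).

The module exposes both a scalar, single-particle API mirroring these
rules one call at a time (:func:`advect_diffuse_step`,
:func:`handle_land`, :func:`check_settlement`) and the vectorized
orchestrator :func:`run_simulation` used for production runs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biology import SpeciesParams, assign_depth, assign_pld, spawning_events
from .connectivity import haversine_distance
from .errors import ConfigurationError
from .forcing import Domain
from .hydro import CurrentSeries, _bilinear_uv, nearest_available_layer

__all__ = [
    "TransportConfig",
    "ParticleState",
    "advect_diffuse_step",
    "handle_land",
    "check_settlement",
    "run_simulation",
    "step_positions",
    "EARTH_RADIUS_M",
    "FATES",
]

EARTH_RADIUS_M = 6_378_137.0
DEG = math.pi / 180.0

FATES = ("settled", "dead", "expired", "left_domain")


@dataclass(frozen=True)
class TransportConfig:
    """Physical and numerical knobs of a transport run.

    dt : timestep in seconds (default 2 h).
    diffusion : horizontal diffusion constant D in m²/s.
    settlement_radius : settlement-zone radius around a site, m.
    n_larvae : per-species larval budget (desk scale).
    mortality / settlement : stage switches, both on for production
        runs; disabling settlement turns the run into a pure
        survival/transport experiment.
    continuous_competency : when True, settlement is tested every step
        from the species minimum PLD onward instead of once at the
        assigned PLD (sensitivity alternative).
    """

    dt: float = 7200.0
    diffusion: float = 0.2
    settlement_radius: float = 1000.0
    seed: int = 0
    n_larvae: Optional[int] = None
    mortality: bool = True
    settlement: bool = True
    continuous_competency: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.diffusion < 0:
            raise ConfigurationError("diffusion must be non-negative")
        if self.settlement_radius <= 0:
            raise ConfigurationError("settlement_radius must be positive")


@dataclass
class ParticleState:
    """A single larva's trajectory state (scalar API)."""

    larva_id: str
    species: SpeciesParams
    origin_site: str
    lon: float
    lat: float
    target_depth: float
    layer: int
    age_days: float = 0.0
    assigned_pld: float = 0.0
    stage: str = "larva"          # "egg" | "larva"
    status: str = "active"        # "active" | terminal fates


def step_positions(lon, lat, u, v, cfg: TransportConfig, rng: np.random.Generator):
    """Advection + random-walk displacement for arrays of positions.

    Returns candidate (lon, lat) after one dt.  The Gaussian kick has
    per-axis standard deviation sqrt(2·D·dt) meters.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    sigma = math.sqrt(2.0 * cfg.diffusion * cfg.dt)
    dx = np.asarray(u) * cfg.dt + rng.normal(0.0, sigma, size=lon.shape)
    dy = np.asarray(v) * cfg.dt + rng.normal(0.0, sigma, size=lat.shape)
    new_lat = lat + dy / EARTH_RADIUS_M / DEG
    new_lon = lon + dx / (EARTH_RADIUS_M * np.cos(lat * DEG)) / DEG
    return new_lon, new_lat


def advect_diffuse_step(
    state: ParticleState,
    series: CurrentSeries,
    cfg: TransportConfig,
    rng: np.random.Generator,
    time: Optional[datetime] = None,
) -> ParticleState:
    """One advection–diffusion step for a single particle.

    Moves the particle, marks it ``left_domain`` if it exits the grid
    extent, and re-clamps its layer to the bathymetry at the new
    position.  Land rejection is a separate rule (:func:`handle_land`).
    """
    if state.status != "active":
        raise ValueError("particle is not active")
    time = time if time is not None else series.start
    day = series.day_index(time)
    u, v, dry = _bilinear_uv(series, state.lon, state.lat, state.layer, day)
    u = np.where(dry, 0.0, u)
    v = np.where(dry, 0.0, v)
    new_lon, new_lat = step_positions(state.lon, state.lat, u, v, cfg, rng)
    new_lon, new_lat = float(new_lon[0]), float(new_lat[0])
    if not bool(series.grid.contains(new_lon, new_lat)):
        return replace(state, lon=new_lon, lat=new_lat, status="left_domain")
    iy, ix = series.grid.cell_index(new_lon, new_lat)
    bathy = series.bathymetry[int(iy), int(ix)]
    layer = state.layer
    if np.isfinite(bathy) and bathy > 0:
        layer = int(nearest_available_layer(state.target_depth, float(bathy), series.grid).index)
    return replace(state, lon=new_lon, lat=new_lat, layer=layer)


def handle_land(previous_lonlat, candidate_lonlat, domain: Domain):
    """Reject moves onto land: a candidate in a land cell returns the
    previous position, otherwise the candidate is accepted."""
    lon, lat = candidate_lonlat
    if bool(domain.grid.contains(lon, lat)):
        iy, ix = domain.grid.cell_index(lon, lat)
        if domain.land_mask[int(iy), int(ix)]:
            return previous_lonlat
    return candidate_lonlat


def check_settlement(state: ParticleState, sites: pd.DataFrame, cfg: TransportConfig) -> Optional[str]:
    """Nearest habitat-suitable site within the settlement radius, or None.

    None means the larva has reached its PLD outside every settlement
    zone and is removed from the model (``expired``).
    """
    suitable = sites[sites["habitat_type"].isin(state.species.habitat_set)]
    if suitable.empty:
        return None
    d = haversine_distance(state.lon, state.lat, suitable["lon"].to_numpy(), suitable["lat"].to_numpy())
    k = int(np.argmin(d))
    if d[k] <= cfg.settlement_radius:
        return str(suitable["site_id"].iloc[k])
    return None


# ---------------------------------------------------------------------------
# Vectorized run
# ---------------------------------------------------------------------------

_PENDING, _ACTIVE, _SETTLED, _DEAD, _EXPIRED, _LEFT = range(6)
_FATE_NAME = {_SETTLED: "settled", _DEAD: "dead", _EXPIRED: "expired", _LEFT: "left_domain"}


def _species_rng(seed: int, name: str) -> np.random.Generator:
    # independent, order-stable stream per (master seed, species)
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())]))


def run_simulation(
    domain: Domain,
    series: CurrentSeries,
    sites: pd.DataFrame,
    species_list: Sequence[SpeciesParams],
    cfg: TransportConfig,
) -> pd.DataFrame:
    """Simulate every species start-to-finish and return settlement records.

    Each species runs separately: spawn events are generated over the
    part of the series that still leaves room for the species' maximum
    PLD, larvae are released and stepped (buoyant-egg phase first where
    applicable), thinned by mortality, and tested for settlement at
    their assigned PLD.  Every larva ends in exactly one terminal fate.

    Returns a DataFrame with one row per larva: larva_id, species,
    origin_site, settle_site (empty if unsettled), fate,
    spawn_datetime, end_datetime, dispersal_distance_m (origin→settle
    site; NaN if unsettled), final_lon, final_lat, displacement_m
    (origin→final position).
    """
    frames = [_run_one_species(domain, series, sites, sp, cfg) for sp in species_list]
    frames = [f for f in frames if len(f)]
    if not frames:
        return _empty_records()
    return pd.concat(frames, ignore_index=True)


def _empty_records() -> pd.DataFrame:
    cols = ["larva_id", "species", "origin_site", "settle_site", "fate", "spawn_datetime",
            "end_datetime", "dispersal_distance_m", "final_lon", "final_lat", "displacement_m"]
    return pd.DataFrame(columns=cols)


def _run_one_species(
    domain: Domain,
    series: CurrentSeries,
    sites: pd.DataFrame,
    sp: SpeciesParams,
    cfg: TransportConfig,
) -> pd.DataFrame:
    g = series.grid
    pld_max_s = sp.pld_max * 86400.0
    span_s = series.n_days * 86400.0
    spawn_end = series.start + timedelta(seconds=span_s - pld_max_s)
    if spawn_end <= series.start:
        raise ConfigurationError(
            f"current series ({series.n_days} d) shorter than maximum PLD of {sp.name} ({sp.pld_max} d)")

    rng = _species_rng(cfg.seed, sp.name)
    budget = cfg.n_larvae if cfg.n_larvae is not None else sp.n_larvae
    focal = domain.focal_island.name
    spawn_sites = sites[(sites["island_id"] == focal) & sites["habitat_type"].isin(sp.habitat_set)]
    events = spawning_events(sp, spawn_sites, series.start, spawn_end,
                             seed=int(rng.integers(0, 2**31)), total_larvae=budget)
    if not events:
        return _empty_records()

    site_lookup = sites.set_index("site_id")
    suitable = sites[sites["habitat_type"].isin(sp.habitat_set)]
    s_lon = suitable["lon"].to_numpy()
    s_lat = suitable["lat"].to_numpy()
    s_ids = suitable["site_id"].to_numpy()

    # --- expand events to particle arrays -------------------------------
    n = sum(e.n_released for e in events)
    origin = np.concatenate([[e.site_id] * e.n_released for e in events])
    spawn_s = np.concatenate([[series.seconds_since_start(e.datetime)] * e.n_released for e in events])
    lon = site_lookup.loc[origin, "lon"].to_numpy(dtype=float).copy()
    lat = site_lookup.loc[origin, "lat"].to_numpy(dtype=float).copy()
    origin_lon = lon.copy()
    origin_lat = lat.copy()
    pld_s = np.asarray(assign_pld(sp, rng, size=n), dtype=float) * 86400.0
    stage_egg = np.full(n, sp.egg_phase)
    if sp.egg_phase:
        depth = assign_depth(sp, "egg", rng, size=n)
    else:
        depth = np.asarray(assign_depth(sp, "larva", rng, size=n), dtype=float)
    iy, ix = g.cell_index(lon, lat)
    bathy0 = np.nan_to_num(series.bathymetry[iy, ix], nan=float(g.layer_edges[-1]))
    bathy0 = np.maximum(bathy0, 1.0)
    layer = np.asarray(nearest_available_layer(depth, bathy0, g), dtype=int)
    age_s = np.zeros(n)
    status = np.full(n, _PENDING, dtype=np.int8)
    settle_idx = np.full(n, -1, dtype=int)
    end_s = np.full(n, np.nan)

    if cfg.mortality:
        half_life_s = sp.half_life_days * 86400.0
        p_die = 1.0 - 2.0 ** (-cfg.dt / half_life_s)
    else:
        p_die = 0.0
    pld_min_s = sp.pld_min * 86400.0
    wet = ~domain.land_mask

    t = float(np.min(spawn_s))
    t_stop = float(np.max(spawn_s) + pld_max_s) + cfg.dt
    while t <= t_stop:
        np.putmask(status, (status == _PENDING) & (spawn_s <= t), _ACTIVE)
        act = np.flatnonzero(status == _ACTIVE)
        if act.size == 0:
            if not np.any(status == _PENDING):
                break
            t += cfg.dt
            continue

        day = min(int(t // 86400.0), series.n_days - 1)
        u = np.zeros(act.size)
        v = np.zeros(act.size)
        for lyr in np.unique(layer[act]):
            sel = layer[act] == lyr
            uu, vv, dry = _bilinear_uv(series, lon[act[sel]], lat[act[sel]], int(lyr), day)
            u[sel] = np.where(dry, 0.0, uu)
            v[sel] = np.where(dry, 0.0, vv)

        cand_lon, cand_lat = step_positions(lon[act], lat[act], u, v, cfg, rng)

        # domain exit terminates; land rejects the move
        out = ~g.contains(cand_lon, cand_lat)
        ciy, cix = g.cell_index(np.clip(cand_lon, g.lon_min, g.lon_max),
                                np.clip(cand_lat, g.lat_min, g.lat_max))
        on_land = wet[ciy, cix] == False  # noqa: E712
        keep = ~out & ~on_land
        lon[act[keep]] = cand_lon[keep]
        lat[act[keep]] = cand_lat[keep]
        status[act[out]] = _LEFT
        end_s[act[out]] = t + cfg.dt
        lon[act[out]] = cand_lon[out]
        lat[act[out]] = cand_lat[out]

        moved = act[keep]
        if moved.size:
            b = series.bathymetry[ciy[keep], cix[keep]]
            b = np.maximum(np.nan_to_num(b, nan=float(g.layer_edges[-1])), 1.0)
            layer[moved] = nearest_available_layer(depth[moved], b, g)

        alive = act[~out]
        if cfg.mortality and alive.size:
            dies = rng.uniform(size=alive.size) < p_die
            status[alive[dies]] = _DEAD
            end_s[alive[dies]] = t + cfg.dt
            alive = alive[~dies]

        age_s[alive] += cfg.dt

        # egg hatches to larva after 24 h, takes its pelagic depth
        if sp.egg_phase:
            hatch = alive[stage_egg[alive] & (age_s[alive] >= 86400.0)]
            if hatch.size:
                stage_egg[hatch] = False
                depth[hatch] = assign_depth(sp, "larva", rng, size=hatch.size)
                hiy, hix = g.cell_index(lon[hatch], lat[hatch])
                b = np.maximum(np.nan_to_num(series.bathymetry[hiy, hix],
                                             nan=float(g.layer_edges[-1])), 1.0)
                layer[hatch] = nearest_available_layer(depth[hatch], b, g)

        if cfg.settlement and cfg.continuous_competency:
            ready = alive[age_s[alive] >= pld_min_s]
            if ready.size and s_lon.size:
                hit, site_k = _nearest_site_hits(lon[ready], lat[ready], s_lon, s_lat, cfg.settlement_radius)
                st = ready[hit]
                status[st] = _SETTLED
                settle_idx[st] = site_k[hit]
                end_s[st] = t + cfg.dt
                alive = alive[~np.isin(alive, st)]

        due = alive[age_s[alive] >= pld_s[alive]]
        if due.size:
            if cfg.settlement and s_lon.size:
                hit, site_k = _nearest_site_hits(lon[due], lat[due], s_lon, s_lat, cfg.settlement_radius)
                st = due[hit]
                status[st] = _SETTLED
                settle_idx[st] = site_k[hit]
                end_s[st] = t + cfg.dt
                ex = due[~hit]
            else:
                ex = due
            status[ex] = _EXPIRED
            end_s[ex] = t + cfg.dt

        t += cfg.dt

    leftover = status <= _ACTIVE
    status[leftover] = _EXPIRED
    end_s[leftover] = t

    settle_site = np.where(settle_idx >= 0, s_ids[np.maximum(settle_idx, 0)], "")
    disp = haversine_distance(origin_lon, origin_lat, lon, lat)
    settled = settle_idx >= 0
    dist = np.full(n, np.nan)
    if settled.any():
        dist[settled] = haversine_distance(
            origin_lon[settled], origin_lat[settled],
            s_lon[settle_idx[settled]], s_lat[settle_idx[settled]])

    start_ts = pd.Timestamp(series.start)
    return pd.DataFrame(
        {
            "larva_id": [f"{sp.name}:{i}" for i in range(n)],
            "species": sp.name,
            "origin_site": origin,
            "settle_site": settle_site,
            "fate": [_FATE_NAME[s] for s in status],
            "spawn_datetime": start_ts + pd.to_timedelta(spawn_s, unit="s"),
            "end_datetime": start_ts + pd.to_timedelta(end_s, unit="s"),
            "dispersal_distance_m": dist,
            "final_lon": lon,
            "final_lat": lat,
            "displacement_m": disp,
        }
    )


def _nearest_site_hits(lon, lat, s_lon, s_lat, radius_m):
    """(within-radius mask, nearest-site index) for each query point."""
    d = haversine_distance(lon[:, None], lat[:, None], s_lon[None, :], s_lat[None, :])
    k = np.argmin(d, axis=1)
    dmin = d[np.arange(len(lon)), k]
    return dmin <= radius_m, k
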