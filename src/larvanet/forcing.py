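"""Synthetic ocean forcing, island geography, and habitat-site generation.

Downstream stages (transport, connectivity, network analysis) consume
gridded daily currents, a land mask with bathymetry, and a table of
shoreline habitat sites pooled into regions.  This module fabricates all
three with the structural properties those stages assume — a focal
island ringed by habitat sites grouped into regions of 2–11 sites,
optional neighbor islands that act as settle-only "exogenous sinks",
and layered daily current snapshots built from simple analytic flow
components (uniform drift, solid-body gyre, alongshore jet) — so the
full pipeline runs and is testable without any external ocean-model or
GIS download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError
from .hydro import CurrentSeries, GridSpec

__all__ = [
    "IslandSpec",
    "Domain",
    "HabitatSite",
    "UniformFlow",
    "SolidBodyGyre",
    "AlongshoreFlow",
    "CompositeFlow",
    "make_island_domain",
    "make_current_series",
    "make_habitat_sites",
    "write_sites",
    "read_sites",
    "HABITAT_TYPES",
    "DEFAULT_START",
]

EARTH_RADIUS_M = 6_378_137.0
DEG = math.pi / 180.0

HABITAT_TYPES = ("reef", "sand", "rock", "rubble", "pavement", "intertidal")

#: Default model start date (day-of-year 1 keeps spawning calendars simple).
DEFAULT_START = datetime(2011, 1, 1)


def _local_xy_m(lon, lat, lon0: float, lat0: float):
    """Local equirectangular offsets (east, north) in meters from (lon0, lat0)."""
    dx = (np.asarray(lon) - lon0) * DEG * EARTH_RADIUS_M * math.cos(lat0 * DEG)
    dy = (np.asarray(lat) - lat0) * DEG * EARTH_RADIUS_M
    return dx, dy


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IslandSpec:
    """A circular/elliptical island: center (°E, °N) and radius in m."""

    name: str
    lon: float
    lat: float
    radius_m: float
    radius_lat_m: Optional[float] = None  # ellipse north-south semi-axis
    focal: bool = False

    def shore_distance_m(self, lon, lat):
        """Signed distance (m) from the island shoreline; negative inland."""
        dx, dy = _local_xy_m(lon, lat, self.lon, self.lat)
        ry = self.radius_lat_m or self.radius_m
        # scaled radial coordinate: 1 on the shoreline ellipse
        rho = np.sqrt((dx / self.radius_m) ** 2 + (dy / ry) ** 2)
        eff = min(self.radius_m, ry)
        return (rho - 1.0) * eff


@dataclass
class Domain:
    """Grid, land mask, bathymetry, and labeled islands.

    ``island_labels`` assigns every land cell the (1-based) index of its
    island in ``islands``; water cells are 0.  ``shore_distance_m`` is
    the distance of each cell center to the nearest island shoreline
    (negative inland), used for site placement and alongshore flows.
    """

    grid: GridSpec
    land_mask: np.ndarray
    bathymetry: np.ndarray
    islands: list[IslandSpec]
    island_labels: np.ndarray
    shore_distance_m: np.ndarray

    @property
    def focal_island(self) -> IslandSpec:
        for isl in self.islands:
            if isl.focal:
                return isl
        return self.islands[0]

    @property
    def n_water_cells(self) -> int:
        return int((~self.land_mask).sum())


def make_island_domain(
    grid: GridSpec,
    islands: Sequence[IslandSpec],
    slope: float = 0.05,
    max_depth_m: float = 1500.0,
    shoreline_depth_m: float = 2.0,
) -> Domain:
    """Build a Domain with circular/elliptical islands on ``grid``.

    Bathymetry deepens linearly (``slope`` m per m) with distance from
    the nearest shoreline, from ``shoreline_depth_m`` at the coast up to
    ``max_depth_m``, so depth along any offshore ray is non-decreasing.

    Raises
    ------
    ConfigurationError
        If islands overlap, an island radius exceeds half the domain
        extent, or fewer than two water cells remain.
    """
    if not islands:
        raise ConfigurationError("at least one island required")
    half_lon_m = (grid.lon_max - grid.lon_min) / 2 * DEG * EARTH_RADIUS_M * math.cos(grid.lat_centers.mean() * DEG)
    half_lat_m = (grid.lat_max - grid.lat_min) / 2 * DEG * EARTH_RADIUS_M
    for isl in islands:
        if isl.radius_m >= min(half_lon_m, half_lat_m):
            raise ConfigurationError(f"island {isl.name!r} radius exceeds domain half-extent")

    LON, LAT = np.meshgrid(grid.lon_centers, grid.lat_centers)
    dists = np.stack([isl.shore_distance_m(LON, LAT) for isl in islands])
    shore = dists.min(axis=0)
    land = shore < 0.0

    labels, n_found = ndimage.label(land)
    if n_found != len(islands):
        raise ConfigurationError(
            f"expected {len(islands)} separate islands, found {n_found} land components "
            "(islands overlap or fall below grid resolution)"
        )
    # relabel components so label k+1 <-> islands[k]
    relabeled = np.zeros_like(labels)
    for k, isl in enumerate(islands):
        iy, ix = grid.cell_index(isl.lon, isl.lat)
        comp = labels[int(iy), int(ix)]
        if comp == 0 or np.any(relabeled[labels == comp] != 0):
            raise ConfigurationError(f"island {isl.name!r} center is not on its own land component")
        relabeled[labels == comp] = k + 1

    bathy = np.where(land, np.nan, np.minimum(max_depth_m, shoreline_depth_m + slope * np.maximum(shore, 0.0)))
    dom = Domain(grid=grid, land_mask=land, bathymetry=bathy, islands=list(islands),
                 island_labels=relabeled, shore_distance_m=shore)
    if dom.n_water_cells < 2:
        raise ConfigurationError("domain has fewer than 2 water cells")
    return dom


# ---------------------------------------------------------------------------
# Flow components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniformFlow:
    """Spatially constant drift (u0 east, v0 north) in m/s."""

    u0: float
    v0: float

    def evaluate(self, LON, LAT, domain: Optional[Domain] = None):
        return np.full_like(LON, self.u0, dtype=float), np.full_like(LON, self.v0, dtype=float)


@dataclass(frozen=True)
class SolidBodyGyre:
    """Solid-body rotation about (lon, lat): tangential speed ω·r inside
    ``radius_m``, decaying as a Rankine vortex (ω·R²/r) outside.

    Positive ``omega`` (s⁻¹) turns counterclockwise; speed is zero at
    the gyre center.
    """

    lon: float
    lat: float
    omega: float
    radius_m: float = 50_000.0

    def evaluate(self, LON, LAT, domain: Optional[Domain] = None):
        dx, dy = _local_xy_m(LON, LAT, self.lon, self.lat)
        r = np.hypot(dx, dy)
        inside = r <= self.radius_m
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(inside, self.omega, self.omega * self.radius_m**2 / np.where(r == 0, 1.0, r**2))
        u = -scale * dy
        v = scale * dx
        return u, v


@dataclass(frozen=True)
class AlongshoreFlow:
    """Current flowing along the focal-island shoreline.

    Tangential to the shoreline (counterclockwise for positive
    ``speed``), with magnitude ``|speed|`` at the coast decaying as
    exp(−d/decay_scale) with offshore distance d.  Requires a Domain.
    """

    speed: float
    decay_scale_m: float = 20_000.0

    def evaluate(self, LON, LAT, domain: Optional[Domain] = None):
        if domain is None:
            raise ConfigurationError("AlongshoreFlow requires a domain")
        isl = domain.focal_island
        dx, dy = _local_xy_m(LON, LAT, isl.lon, isl.lat)
        r = np.hypot(dx, dy)
        r = np.where(r == 0, 1.0, r)
        d = np.maximum(isl.shore_distance_m(LON, LAT), 0.0)
        mag = self.speed * np.exp(-d / self.decay_scale_m)
        return -mag * dy / r, mag * dx / r


@dataclass(frozen=True)
class CompositeFlow:
    """Pointwise sum of flow components."""

    components: tuple = ()

    def evaluate(self, LON, LAT, domain: Optional[Domain] = None):
        U = np.zeros_like(LON, dtype=float)
        V = np.zeros_like(LAT, dtype=float)
        for c in self.components:
            u, v = c.evaluate(LON, LAT, domain)
            U += u
            V += v
        return U, V


def make_current_series(
    grid: GridSpec,
    flow_spec,
    n_days: int,
    seed: Optional[int] = None,
    domain: Optional[Domain] = None,
    start: datetime = DEFAULT_START,
    noise_std: float = 0.0,
) -> CurrentSeries:
    """Daily layered (u, v) snapshots from an analytic flow descriptor.

    The base flow is steady and identical across layers; with
    ``noise_std > 0`` a seeded Gaussian day-to-day perturbation (m/s,
    shared across layers) is added so successive snapshots differ.
    Velocities are zero on land and finite everywhere.  With no domain,
    the whole grid is open water of ``open_water_depth`` = deepest layer
    bottom.
    """
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    LON, LAT = np.meshgrid(grid.lon_centers, grid.lat_centers)
    U, V = flow_spec.evaluate(LON, LAT, domain)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if domain is not None:
        if domain.n_water_cells < 2:
            raise ConfigurationError("domain has fewer than 2 water cells")
        land = domain.land_mask
        bathy = domain.bathymetry
    else:
        land = np.zeros(LON.shape, dtype=bool)
        bathy = np.full(LON.shape, float(grid.layer_edges[-1]))
    U[land] = 0.0
    V[land] = 0.0
    if not (np.all(np.isfinite(U)) and np.all(np.isfinite(V))):
        raise ConfigurationError("flow specification produced non-finite velocities")

    shape = (n_days, grid.n_layers, grid.n_lat, grid.n_lon)
    if noise_std > 0.0:
        rng = np.random.default_rng(seed)
        pert_u = rng.normal(0.0, noise_std, size=(n_days, grid.n_lat, grid.n_lon))
        pert_v = rng.normal(0.0, noise_std, size=(n_days, grid.n_lat, grid.n_lon))
        pert_u[:, land] = 0.0
        pert_v[:, land] = 0.0
        u = np.broadcast_to((U[None] + pert_u)[:, None], shape)
        v = np.broadcast_to((V[None] + pert_v)[:, None], shape)
    else:
        # steady flow: read-only broadcast views keep memory O(one field)
        u = np.broadcast_to(U[None, None], shape)
        v = np.broadcast_to(V[None, None], shape)
    return CurrentSeries(grid=grid, start=start, u=u, v=v, land_mask=land, bathymetry=bathy)


# ---------------------------------------------------------------------------
# Habitat sites and regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HabitatSite:
    """A shoreline habitat point: location, habitat type, coast, region."""

    site_id: str
    lon: float
    lat: float
    habitat_type: str
    coast: str
    region_id: str
    island_id: str


def _coast_of_bearing(bearing_deg: float) -> str:
    b = bearing_deg % 360.0
    if b < 45 or b >= 315:
        return "N"
    if b < 135:
        return "E"
    if b < 225:
        return "S"
    return "W"


def _run_lengths(n: int, lo: int, hi: int, rng: np.random.Generator) -> list[int]:
    """Split n into runs each within [lo, hi]."""
    if n < lo:
        raise ConfigurationError(f"{n} sites cannot form a region of >= {lo} sites")
    runs = []
    remaining = n
    while remaining > 0:
        k = int(rng.integers(lo, hi + 1))
        if remaining - k < lo and remaining - k != 0:
            k = remaining if remaining <= hi else min(hi, remaining - lo)
        k = min(k, remaining)
        runs.append(k)
        remaining -= k
    return runs


def _allocate_habitats(n_regions: int, types: list, probs: np.ndarray, rng: np.random.Generator) -> list:
    """Region habitats matching the requested mix as closely as possible.

    Counts follow largest-remainder apportionment of ``probs`` over the
    regions (so every requested type appears when there are at least as
    many regions as types), then the sequence is shuffled.
    """
    ideal = probs * n_regions
    counts = np.floor(ideal).astype(int)
    short = n_regions - counts.sum()
    if short > 0:
        order = np.argsort(-(ideal - counts))
        counts[order[:short]] += 1
    # with few regions, guarantee each requested type one slot if possible
    while n_regions >= len(types) and np.any((counts == 0) & (probs > 0)):
        take = int(np.argmax(counts))
        give = int(np.flatnonzero((counts == 0) & (probs > 0))[0])
        counts[take] -= 1
        counts[give] += 1
    habs = [t for t, c in zip(types, counts) for _ in range(c)]
    rng.shuffle(habs)
    return habs


def make_habitat_sites(
    domain: Domain,
    n_sites: int = 48,
    habitat_mix: Optional[dict] = None,
    region_size_bounds: tuple[int, int] = (2, 11),
    seed: int = 0,
    max_shore_distance_m: float = 1000.0,
) -> pd.DataFrame:
    """Place habitat sites around every island's shoreline ring.

    Sites sit evenly spaced in bearing around each island, in water,
    within ``max_shore_distance_m`` (1 km) of the shoreline.  Each site
    gets a coast (N/E/S/W bearing quadrant from the island center) and a
    habitat type; contiguous runs of sites form regions whose sizes fall
    inside ``region_size_bounds``.  The focal island receives
    ``n_sites``; neighbor islands receive a share proportional to their
    radius (these act as settle-only exogenous sinks downstream).

    Returns a DataFrame with columns site_id, lon, lat, habitat_type,
    coast, region_id, island_id.  Generation is reproducible bit-for-bit
    for a fixed seed.
    """
    lo, hi = region_size_bounds
    if not (1 <= lo <= hi):
        raise ConfigurationError("invalid region_size_bounds")
    if n_sites < lo:
        raise ConfigurationError("n_sites too small for region_size_bounds")
    mix = habitat_mix or {t: 1.0 / len(HABITAT_TYPES) for t in HABITAT_TYPES}
    types = sorted(mix)
    probs = np.array([mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    g = domain.grid
    focal = domain.focal_island

    rows = []
    region_counter = 0
    for isl in domain.islands:
        n_isl = n_sites if isl is focal or isl.focal else max(
            2 * lo, int(round(n_sites * isl.radius_m / focal.radius_m)))
        ry = isl.radius_lat_m or isl.radius_m
        placed = []
        for j in range(n_isl):
            theta = 2 * math.pi * j / n_isl  # bearing from north, clockwise
            bdx, bdy = math.sin(theta), math.cos(theta)
            # walk outward from just off the shoreline until the cell is wet
            pos = None
            for step_frac in np.arange(0.25, 1.01, 0.125):
                off = step_frac * max_shore_distance_m
                px = isl.radius_m * bdx * (1 + off / isl.radius_m)
                py = ry * bdy * (1 + off / ry)
                lon = isl.lon + px / (EARTH_RADIUS_M * math.cos(isl.lat * DEG)) / DEG
                lat = isl.lat + py / EARTH_RADIUS_M / DEG
                if not bool(g.contains(lon, lat)):
                    break
                iy, ix = g.cell_index(lon, lat)
                if not domain.land_mask[int(iy), int(ix)]:
                    pos = (lon, lat, math.degrees(theta))
                    break
            if pos is not None:
                placed.append(pos)
        if len(placed) < lo:
            raise ConfigurationError(
                f"could not place >= {lo} sites on island {isl.name!r}; refine the grid")

        runs = _run_lengths(len(placed), lo, hi, rng)
        habs = _allocate_habitats(len(runs), types, probs, rng)
        k = 0
        for run_len, hab in zip(runs, habs):
            region_counter += 1
            rid = f"{isl.name}-R{region_counter:02d}"
            for _ in range(run_len):
                lon, lat, bearing = placed[k]
                rows.append(
                    {
                        "site_id": f"{isl.name}-S{k:03d}",
                        "lon": lon,
                        "lat": lat,
                        "habitat_type": hab,
                        "coast": _coast_of_bearing(bearing),
                        "region_id": rid,
                        "island_id": isl.name,
                    }
                )
                k += 1
    return pd.DataFrame(rows)


def write_sites(sites: pd.DataFrame, path, **meta) -> None:
    """Write the site table as CSV; ``meta`` entries go in a # header line."""
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in sorted(meta.items())) + "\n")
        sites.to_csv(fh, index=False)


def read_sites(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def species_table() -> pd.DataFrame:
    """The packaged 11-species life-history parameter table (see biology)."""
    from .biology import load_species_table

    return load_species_table()
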