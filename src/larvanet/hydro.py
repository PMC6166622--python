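"""Layered ocean-current data model and space/time velocity lookup.

The transport stepper consumes daily snapshots of horizontal velocity
(``u`` eastward, ``v`` northward, m/s) on a regular longitude/latitude
grid divided into depth layers whose thickness is non-decreasing with
depth (5 m at the surface).  Vertical velocity is deliberately absent
from the contract: a larva holds a fixed target depth, and only its
layer assignment changes as it moves over shallower or deeper water
(clamped to the local bathymetry).

Longitudes follow the oceanographic [0, 360) °E convention.  Velocities
are defined at cell centers; horizontal lookup is bilinear over the four
surrounding centers with dry (land) corners dropped from the stencil and
the remaining weights renormalized.  Fields are held constant within
each day: no temporal interpolation is applied between daily snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ConfigurationError, OnLandError

__all__ = [
    "GridSpec",
    "LayerIndex",
    "CurrentSeries",
    "DEFAULT_LAYER_THICKNESS_M",
    "default_layer_edges",
    "layer_edges_50",
    "interpolate_velocity",
    "nearest_available_layer",
]

#: Desk-scale default vertical scheme: 10 layers with thickness
#: non-decreasing from 5 m at the surface, structurally mirroring an
#: ocean-model grid that refines toward the surface.
DEFAULT_LAYER_THICKNESS_M = (5.0, 10.0, 15.0, 25.0, 50.0, 75.0, 100.0, 150.0, 300.0, 510.0)


def default_layer_edges() -> tuple[float, ...]:
    """Edges (m, positive down) of the default 10-layer scheme."""
    return tuple(np.concatenate([[0.0], np.cumsum(DEFAULT_LAYER_THICKNESS_M)]))


def layer_edges_50() -> tuple[float, ...]:
    """A 50-layer scheme growing geometrically from 5 m to 510 m thickness.

    Layer thickness interpolates geometrically between a 5-m surface
    layer and a 510-m bottom layer, the configuration used by
    high-resolution regional circulation models of island wakes.
    """
    i = np.arange(50)
    thickness = 5.0 * (510.0 / 5.0) ** (i / 49.0)
    return tuple(np.concatenate([[0.0], np.cumsum(thickness)]))


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid with a layered vertical axis.

    Parameters
    ----------
    lon_min, lon_max : float
        Longitude extent in °E, [0, 360) convention.
    lat_min, lat_max : float
        Latitude extent in °N.
    cell_size : float
        Cell edge length in degrees (square cells).
    layer_edges : tuple of float
        Depth-layer boundaries in m, strictly increasing from 0; the
        layer i spans [edges[i], edges[i+1]).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float
    layer_edges: tuple[float, ...] = field(default_factory=default_layer_edges)

    def __post_init__(self) -> None:
        if not (self.lon_max > self.lon_min and self.lat_max > self.lat_min):
            raise ConfigurationError("grid extents must be positive")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        edges = np.asarray(self.layer_edges, dtype=float)
        if edges.size < 3:
            raise ConfigurationError("at least 2 depth layers required")
        if edges[0] != 0.0 or np.any(np.diff(edges) <= 0):
            raise ConfigurationError("layer_edges must strictly increase from 0")

    # -- horizontal axis -------------------------------------------------
    @property
    def n_lon(self) -> int:
        return max(1, int(round((self.lon_max - self.lon_min) / self.cell_size)))

    @property
    def n_lat(self) -> int:
        return max(1, int(round((self.lat_max - self.lat_min) / self.cell_size)))

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.cell_size

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.cell_size

    def cell_index(self, lon, lat):
        """Indices (iy, ix) of the cell containing each point (clipped to grid)."""
        ix = np.clip(((np.asarray(lon) - self.lon_min) / self.cell_size).astype(int), 0, self.n_lon - 1)
        iy = np.clip(((np.asarray(lat) - self.lat_min) / self.cell_size).astype(int), 0, self.n_lat - 1)
        return iy, ix

    def contains(self, lon, lat):
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (lon >= self.lon_min) & (lon <= self.lon_max) & (lat >= self.lat_min) & (lat <= self.lat_max)

    # -- vertical axis ---------------------------------------------------
    @property
    def n_layers(self) -> int:
        return len(self.layer_edges) - 1

    @property
    def layer_tops(self) -> np.ndarray:
        return np.asarray(self.layer_edges[:-1], dtype=float)

    @property
    def layer_bottoms(self) -> np.ndarray:
        return np.asarray(self.layer_edges[1:], dtype=float)

    def layer(self, index: int) -> "LayerIndex":
        return LayerIndex(index, float(self.layer_edges[index]), float(self.layer_edges[index + 1]))

    def layer_for_depth(self, depth) -> np.ndarray:
        """Layer index containing ``depth``; a boundary depth is assigned downward."""
        edges = np.asarray(self.layer_edges, dtype=float)
        idx = np.searchsorted(edges, np.asarray(depth, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.n_layers - 1)


@dataclass(frozen=True)
class LayerIndex:
    """One vertical layer: ordinal position and depth bounds in m."""

    index: int
    top: float
    bottom: float

    def __post_init__(self) -> None:
        if not self.top < self.bottom:
            raise ConfigurationError("layer top must be above bottom")


@dataclass
class CurrentSeries:
    """Daily (u, v) snapshots per depth layer with land mask and bathymetry.

    ``u``/``v`` have shape (n_days, n_layers, n_lat, n_lon), m/s, and are
    zero on land.  ``bathymetry`` is in m positive down, NaN on land.
    Arrays may be broadcast (read-only) views when the flow is steady.
    """

    grid: GridSpec
    start: datetime
    u: np.ndarray
    v: np.ndarray
    land_mask: np.ndarray
    bathymetry: np.ndarray

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape or self.u.ndim != 4:
            raise ConfigurationError("u and v must both be (day, layer, lat, lon)")
        if self.u.shape[1] != self.grid.n_layers:
            raise ConfigurationError("layer dimension does not match grid")
        if self.u.shape[2:] != (self.grid.n_lat, self.grid.n_lon):
            raise ConfigurationError("horizontal dimensions do not match grid")
        wet = ~self.land_mask
        if not (np.all(np.isfinite(self.u[:, :, wet])) and np.all(np.isfinite(self.v[:, :, wet]))):
            raise ConfigurationError("velocities must be finite on water")

    @property
    def n_days(self) -> int:
        return self.u.shape[0]

    @property
    def days(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_days, freq="D")

    @property
    def end(self) -> datetime:
        return self.start + timedelta(days=self.n_days)

    def seconds_since_start(self, time: datetime) -> float:
        return (time - self.start).total_seconds()

    def day_index(self, time: datetime) -> int:
        """Day whose (held-constant) snapshot applies at ``time``."""
        s = self.seconds_since_start(time)
        if s < 0 or s > self.n_days * 86400.0:
            raise ValueError(f"time {time} outside series span")
        return min(int(s // 86400.0), self.n_days - 1)

    # -- persistence -----------------------------------------------------
    def to_netcdf(self, path, **attrs) -> None:
        """Write as a NetCDF file with dims (time, layer, lat, lon)."""
        ds = xr.Dataset(
            {
                "u": (("time", "layer", "lat", "lon"), np.ascontiguousarray(self.u)),
                "v": (("time", "layer", "lat", "lon"), np.ascontiguousarray(self.v)),
                "mask": (("lat", "lon"), self.land_mask.astype(np.int8)),
                "bathymetry": (("lat", "lon"), self.bathymetry),
            },
            coords={
                "time": self.days,
                "layer": np.arange(self.grid.n_layers),
                "lat": self.grid.lat_centers,
                "lon": self.grid.lon_centers,
            },
            attrs={
                "cell_size": self.grid.cell_size,
                "lon_min": self.grid.lon_min,
                "lon_max": self.grid.lon_max,
                "lat_min": self.grid.lat_min,
                "lat_max": self.grid.lat_max,
                "layer_edges": list(self.grid.layer_edges),
                **attrs,
            },
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "CurrentSeries":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds.load()
        grid = GridSpec(
            lon_min=float(ds.attrs["lon_min"]),
            lon_max=float(ds.attrs["lon_max"]),
            lat_min=float(ds.attrs["lat_min"]),
            lat_max=float(ds.attrs["lat_max"]),
            cell_size=float(ds.attrs["cell_size"]),
            layer_edges=tuple(float(e) for e in ds.attrs["layer_edges"]),
        )
        start = pd.Timestamp(ds["time"].values[0]).to_pydatetime()
        return cls(
            grid=grid,
            start=start,
            u=np.asarray(ds["u"].values, dtype=float),
            v=np.asarray(ds["v"].values, dtype=float),
            land_mask=np.asarray(ds["mask"].values, dtype=bool),
            bathymetry=np.asarray(ds["bathymetry"].values, dtype=float),
        )


# ---------------------------------------------------------------------------
# Velocity lookup
# ---------------------------------------------------------------------------

def _bilinear_uv(series: CurrentSeries, lon, lat, layer_idx, day_idx):
    """Vectorized bilinear (u, v) lookup with land-aware weight renormalization.

    Returns ``(u, v, dry)`` where ``dry`` marks points whose four
    surrounding cell centers are all land (u, v are NaN there).
    """
    g = series.grid
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    layer_idx = np.broadcast_to(np.atleast_1d(layer_idx), lon.shape)
    day_idx = np.broadcast_to(np.atleast_1d(day_idx), lon.shape)

    x = (lon - g.lon_centers[0]) / g.cell_size
    y = (lat - g.lat_centers[0]) / g.cell_size
    ix0 = np.clip(np.floor(x).astype(int), 0, max(g.n_lon - 2, 0))
    iy0 = np.clip(np.floor(y).astype(int), 0, max(g.n_lat - 2, 0))
    fx = np.clip(x - ix0, 0.0, 1.0)
    fy = np.clip(y - iy0, 0.0, 1.0)
    ix1 = np.minimum(ix0 + 1, g.n_lon - 1)
    iy1 = np.minimum(iy0 + 1, g.n_lat - 1)

    wet = ~series.land_mask
    w = [
        (1 - fx) * (1 - fy) * wet[iy0, ix0],
        fx * (1 - fy) * wet[iy0, ix1],
        (1 - fx) * fy * wet[iy1, ix0],
        fx * fy * wet[iy1, ix1],
    ]
    corners = [(iy0, ix0), (iy0, ix1), (iy1, ix0), (iy1, ix1)]
    total = w[0] + w[1] + w[2] + w[3]
    dry = total <= 0.0
    safe = np.where(dry, 1.0, total)

    u = np.zeros_like(lon)
    v = np.zeros_like(lon)
    for wk, (cy, cx) in zip(w, corners):
        u += wk * series.u[day_idx, layer_idx, cy, cx]
        v += wk * series.v[day_idx, layer_idx, cy, cx]
    u = np.where(dry, np.nan, u / safe)
    v = np.where(dry, np.nan, v / safe)
    return u, v, dry


def interpolate_velocity(series: CurrentSeries, lon: float, lat: float, layer, time: datetime):
    """Horizontal velocity (u, v) in m/s at a point, layer, and time.

    Bilinear over the four surrounding water-cell centers; land corners
    are dropped and the remaining weights renormalized.  The daily field
    is held constant within its day.

    Raises
    ------
    OnLandError
        If all four stencil cells are land.
    ValueError
        If the point is outside the grid extent or the time outside the
        series span.
    """
    if not bool(series.grid.contains(lon, lat)):
        raise ValueError(f"point ({lon}, {lat}) outside grid extent")
    day = series.day_index(time)
    idx = layer.index if isinstance(layer, LayerIndex) else int(layer)
    u, v, dry = _bilinear_uv(series, lon, lat, idx, day)
    if dry[0]:
        raise OnLandError(f"all stencil cells dry at ({lon}, {lat})")
    return float(u[0]), float(v[0])


def nearest_available_layer(target_depth, bathymetry_at_point, grid: GridSpec):
    """Layer assignment for a target depth, clamped to the seabed.

    Returns the layer containing ``target_depth`` when that layer's top
    lies above the seabed; otherwise the deepest layer whose top is
    above the seabed.  A depth on a layer boundary is assigned downward.
    Accepts scalars or arrays; scalar input yields a :class:`LayerIndex`.
    """
    scalar = np.isscalar(target_depth) and np.isscalar(bathymetry_at_point)
    depth = np.atleast_1d(np.asarray(target_depth, dtype=float))
    bathy = np.atleast_1d(np.asarray(bathymetry_at_point, dtype=float))
    if np.any(bathy <= 0):
        raise ValueError("bathymetry must be positive (water point)")
    wanted = grid.layer_for_depth(depth)
    # deepest layer whose top is strictly above the seabed
    deepest = np.searchsorted(grid.layer_tops, bathy, side="left") - 1
    deepest = np.clip(deepest, 0, grid.n_layers - 1)
    out = np.minimum(wanted, deepest)
    if scalar:
        return grid.layer(int(out[0]))
    return out
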