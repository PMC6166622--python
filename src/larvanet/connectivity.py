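"""Connectivity statistics from settlement records.

From the per-larva settlement records this module builds the
origin × destination count matrix S (S[o, s] = settlers at s spawned at
o), and derives the standard site/region statistics of larval
connectivity analysis:

* forward settlement proportion   P_so = S_os / ΣS_o   (row-normalized),
* rearward settlement proportion  P_os = S_os / ΣS_s   (column-normalized),
* local retention                 diag(S) / row sums,
* source–sink index               SSI = (E − I) / (E + I), with exports
  E and imports I counted over *other* sites of the focal island only
  (self-settlement excluded from both; settlement to exogenous neighbor
  islands excluded entirely),
* dispersal-distance kernels and summaries per disperser class, and the
  cross-species Pearson correlations of minimum PLD with settlement
  success and (log-transformed) with mean dispersal distance.

Division by an empty row/column is undefined and propagates as NaN,
never as 0: "no settlers" is missing data, not a perfect sink.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .biology import pld_class
from .errors import DataError

__all__ = [
    "ConnectivityMatrix",
    "haversine_distance",
    "build_matrix",
    "forward_proportion",
    "rearward_proportion",
    "local_retention",
    "source_sink_index",
    "dispersal_stats",
    "pld_correlations",
]

EARTH_RADIUS_M = 6_378_137.0


def haversine_distance(lon1, lat1, lon2, lat2):
    """Great-circle distance in m (Haversine formula, R = 6,378,137 m)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    a = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class ConnectivityMatrix:
    """Counts S[origin, destination] at some aggregation level.

    ``data`` is a DataFrame (rows = origins, columns = destinations).
    ``exogenous`` flags destination labels on non-focal islands, which
    are retained for settlement accounting but excluded from
    island-scale indices.  ``level`` is one of site/region/coast/island.
    """

    data: pd.DataFrame
    level: str
    focal_island: str
    exogenous: frozenset[str]

    @property
    def grand_total(self) -> int:
        return int(self.data.to_numpy().sum())

    def focal_square(self) -> pd.DataFrame:
        """The matrix restricted to focal-island labels on both axes."""
        rows = [r for r in self.data.index if r not in self.exogenous]
        cols = [c for c in self.data.columns if c not in self.exogenous]
        labels = sorted(set(rows) | set(cols))
        return self.data.reindex(index=labels, columns=labels, fill_value=0)


_LEVEL_COLS = {"site": "site_id", "region": "region_id", "coast": "coast", "island": "island_id"}


def build_matrix(
    records: pd.DataFrame,
    sites: pd.DataFrame,
    level: str = "site",
    focal_island: Optional[str] = None,
    species: Optional[str] = None,
) -> ConnectivityMatrix:
    """Count settled larvae into an origin × destination matrix.

    Aggregation ``level``: site, region, coast, or island.  Destination
    labels on islands other than the focal one are kept but flagged
    exogenous.  Unknown site ids in the records raise :class:`DataError`.
    """
    if level not in _LEVEL_COLS:
        raise DataError(f"unknown aggregation level {level!r}")
    if species is not None:
        records = records[records["species"] == species]
    settled = records[records["fate"] == "settled"]

    meta = sites.set_index("site_id")
    unknown = (set(settled["origin_site"]) | set(settled["settle_site"])) - set(meta.index)
    if unknown:
        raise DataError(f"records reference unknown sites: {sorted(unknown)[:5]}")
    if focal_island is None:
        focal_island = str(meta["island_id"].iloc[0])

    col = _LEVEL_COLS[level]

    def label_of(site_ids):
        if level == "site":
            return np.asarray(site_ids)
        if level == "coast":
            # coast labels are per-island; qualify non-focal ones
            isl = meta.loc[site_ids, "island_id"].to_numpy()
            c = meta.loc[site_ids, "coast"].to_numpy()
            return np.where(isl == focal_island, c, isl + ":" + c)
        return meta.loc[site_ids, col].to_numpy()

    origin_all = meta.loc[meta["island_id"] == focal_island]
    origin_labels = sorted(set(label_of(origin_all.index)))
    dest_labels = sorted(set(label_of(meta.index)))

    if settled.empty:
        data = pd.DataFrame(0, index=origin_labels, columns=dest_labels)
    else:
        data = (
            pd.crosstab(label_of(settled["origin_site"]), label_of(settled["settle_site"]))
            .reindex(index=origin_labels, columns=dest_labels, fill_value=0)
        )
    data.index.name = "origin"
    data.columns.name = "destination"
    exo_sites = meta.index[meta["island_id"] != focal_island]
    exogenous = frozenset(label_of(exo_sites)) if len(exo_sites) else frozenset()
    return ConnectivityMatrix(data=data, level=level, focal_island=focal_island, exogenous=exogenous)


def _as_frame(M) -> pd.DataFrame:
    return M.data if isinstance(M, ConnectivityMatrix) else pd.DataFrame(M, dtype=float)


def forward_proportion(M) -> pd.DataFrame:
    """P_so = S_os / ΣS_o: each row scaled by its row total.

    Rows with no settlers are undefined (NaN), not zero.
    """
    S = _as_frame(M).astype(float)
    totals = S.sum(axis=1)
    return S.div(totals.where(totals > 0), axis=0)


def rearward_proportion(M) -> pd.DataFrame:
    """P_os = S_os / ΣS_s: each column scaled by its column total.

    Columns with no settlers are undefined (NaN), not zero.
    """
    S = _as_frame(M).astype(float)
    totals = S.sum(axis=0)
    return S.div(totals.where(totals > 0), axis=1)


def local_retention(M) -> pd.Series:
    """Fraction of each origin's successful settlers that settled back at
    the natal site/region: diag(S) / row sum (NaN where no settlers)."""
    S = _as_frame(M).astype(float)
    common = [i for i in S.index if i in S.columns]
    diag = pd.Series({i: S.at[i, i] for i in common}, dtype=float).reindex(S.index, fill_value=0.0)
    totals = S.sum(axis=1)
    return (diag / totals.where(totals > 0)).rename("local_retention")


def source_sink_index(M: ConnectivityMatrix) -> pd.DataFrame:
    """Per-label exports E, imports I, SSI = (E−I)/(E+I), local retention.

    Exports and imports count settlers exchanged with *other* labels of
    the focal island: self-settlement is excluded from both, and
    settlement to exogenous islands is excluded entirely.  SSI is +1
    for a pure source, −1 for a pure sink, NaN when E + I = 0.
    """
    S = M.focal_square().astype(float)
    diag = pd.Series(np.diag(S), index=S.index)
    E = S.sum(axis=1) - diag
    I = S.sum(axis=0) - diag  # noqa: E741 - the field's symbol
    total = E + I
    ssi = (E - I) / total.where(total > 0)
    out = pd.DataFrame({"exports": E, "imports": I, "ssi": ssi})
    out["local_retention"] = local_retention(M).reindex(out.index)
    out.index.name = M.data.index.name
    return out


def dispersal_stats(
    records: pd.DataFrame,
    species_pld_min: dict[str, float],
    bin_width_m: float = 5000.0,
) -> pd.DataFrame:
    """Dispersal-distance summaries and kernels per disperser class.

    Settled records are pooled by class of the species' minimum PLD
    (short 3–25 d, medium 30–50 d, long 140–270 d).  Returns one row per
    class present: n, mean/sd/median/max distance (m), and the
    fixed-width histogram kernel (bin edges + densities) as object
    columns.  A species absent from ``species_pld_min`` or with a
    minimum PLD outside every class raises :class:`DataError`.
    """
    settled = records[records["fate"] == "settled"].copy()
    classes = {}
    for name in settled["species"].unique():
        if name not in species_pld_min:
            raise DataError(f"no minimum PLD for species {name!r}")
        try:
            classes[name] = pld_class(species_pld_min[name])
        except ValueError as e:
            raise DataError(str(e)) from e
    settled["pld_class"] = settled["species"].map(classes)

    rows = []
    for cls in ("short", "medium", "long"):
        d = settled.loc[settled["pld_class"] == cls, "dispersal_distance_m"].to_numpy(dtype=float)
        if d.size == 0:
            continue
        edges = np.arange(0.0, d.max() + bin_width_m, bin_width_m)
        if len(edges) < 2:
            edges = np.array([0.0, bin_width_m])
        dens, edges = np.histogram(d, bins=edges, density=True)
        rows.append(
            {
                "pld_class": cls,
                "n": d.size,
                "mean_m": float(d.mean()),
                "sd_m": float(d.std(ddof=1)) if d.size > 1 else 0.0,
                "median_m": float(np.median(d)),
                "max_m": float(d.max()),
                "kernel_edges_m": edges,
                "kernel_density": dens,
            }
        )
    return pd.DataFrame(rows).set_index("pld_class") if rows else pd.DataFrame()


def pld_correlations(summary: pd.DataFrame) -> dict[str, float]:
    """Cross-species Pearson correlations against minimum PLD.

    ``summary`` needs one row per species with columns ``pld_min``,
    ``settlement_fraction``, ``mean_distance_m``.  Returns
    ``r_settlement`` (pld_min vs settlement fraction) and
    ``r_distance`` (log_e pld_min vs mean dispersal distance); NaN with
    a flag when fewer than 3 species or zero variance.
    """
    out = {"r_settlement": np.nan, "r_distance": np.nan, "defined": False}
    if len(summary) < 3:
        return out
    x = summary["pld_min"].to_numpy(dtype=float)
    s = summary["settlement_fraction"].to_numpy(dtype=float)
    d = summary["mean_distance_m"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(s) & np.isfinite(d)
    x, s, d = x[ok], s[ok], d[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(s) == 0 or np.std(d) == 0:
        return out
    out["r_settlement"] = float(stats.pearsonr(x, s).statistic)
    out["r_distance"] = float(stats.pearsonr(np.log(x), d).statistic)
    out["defined"] = True
    return out
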