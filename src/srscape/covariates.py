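"""Site x predictor matrix construction and predictor pruning.

Covariate values are read at each site's containing raster cell; where that
cell is nodata the nearest valid cell (great-circle distance on cell
centres) within a search radius is substituted and flagged, mirroring field
practice when coarse covariate sources leave gaps at sampling sites.
Strongly correlated predictor pairs (|Pearson R| above a threshold) are
pruned iteratively before model fitting.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .grids import RasterGrid, haversine_km
from .samples import SampleRecord

#: The standard auxiliary-predictor set for bioavailable-Sr isoscape work:
#: mechanistic bedrock-model quantiles, lithological ages, climate,
#: atmospheric deposition, terrain, and soil properties.
REGISTRY: list[tuple[str, str, str]] = [
    ("r.m1", "median bedrock 87Sr/86Sr model", "ratio"),
    ("r.srsrq1", "1st quartile bedrock 87Sr/86Sr model", "ratio"),
    ("r.srsrq3", "3rd quartile bedrock 87Sr/86Sr model", "ratio"),
    ("r.meanage_geol", "mean lithological-unit age", "Myr"),
    ("r.minage_geol", "minimal lithological-unit age", "Myr"),
    ("r.maxage_geol", "maximal lithological-unit age", "Myr"),
    ("r.age", "terrane age", "Myr"),
    ("r.mat", "mean annual temperature", "degC"),
    ("r.map", "mean annual precipitation", "mm/yr"),
    ("r.pet", "potential evapotranspiration", "mm/yr"),
    ("r.ai", "aridity index", "dimensionless"),
    ("r.salt", "sea-salt deposition", "g/m2/yr"),
    ("r.dust", "dust deposition", "g/m2/yr"),
    ("r.fire", "black-carbon deposition", "kg/m2/s"),
    ("r.foss", "fossil-fuel deposition", "kg/m2/s"),
    ("r.volc", "volcanic deposition", "kg/m2/s"),
    ("r.dist", "distance to coast", "km"),
    ("r.elevation", "elevation", "m"),
    ("r.bouguer", "Bouguer gravity anomaly", "mGal"),
    ("r.GUM", "unconsolidated sediment class", "category"),
    ("r.cec", "cation exchange capacity", "mmol(c)/kg"),
    ("r.ph", "soil pH (H2O, x10)", "pH*10"),
    ("r.phkcl", "soil pH (KCl, x10)", "pH*10"),
    ("r.clay", "clay content", "g/kg"),
    ("r.ocs", "organic carbon stock", "t/ha"),
    ("r.bulk", "bulk density", "cg/cm3"),
]

REGISTRY_NAMES = [name for name, _, _ in REGISTRY]


class ExtractionError(ValueError):
    """A site could not be served a covariate value."""


@dataclasses.dataclass
class CovariateMatrix:
    """Complete sites x predictors matrix with provenance and response."""

    site_ids: list[str]
    names: list[str]
    values: np.ndarray                # (n_sites, n_predictors)
    provenance: np.ndarray            # same shape, "direct" | "nearest-fallback"
    response: np.ndarray              # 87Sr/86Sr per site
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if len(self.site_ids) != n or len(self.names) != p or len(self.response) != n:
            raise ValueError("matrix, ids, names and response dimensions disagree")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariate matrix contains missing values after fallback")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names, index=self.site_ids)

    def subset(self, names: list[str]) -> "CovariateMatrix":
        idx = [self.names.index(n) for n in names]
        return CovariateMatrix(self.site_ids, list(names), self.values[:, idx],
                               self.provenance[:, idx], self.response, self.lon, self.lat)


def _nearest_valid(grid: RasterGrid, lon: float, lat: float,
                   max_km: float) -> tuple[float, float] | None:
    """Exhaustive nearest-valid-cell search; returns (value, distance_km)."""
    mask = grid.valid_mask()
    if not mask.any():
        return None
    lons, lats = grid.cell_centers()
    dist = haversine_km(lon, lat, lons[mask], lats[mask])
    k = int(np.argmin(dist))
    if dist[k] > max_km:
        return None
    return float(grid.values[mask][k]), float(dist[k])


def extract_at_points(stack: dict[str, RasterGrid], sites: list[SampleRecord],
                      max_fallback_km: float = 50.0) -> CovariateMatrix:
    """Extract every covariate at every site, with nearest-value fallback.

    Raises :class:`ExtractionError` naming the site when a site lies outside
    a raster's extent beyond the fallback radius, or when no valid cell is
    within ``max_fallback_km`` of a nodata hit.
    """
    if not stack:
        raise ValueError("empty covariate stack")
    names = list(stack.keys())
    n, p = len(sites), len(names)
    values = np.full((n, p), np.nan)
    provenance = np.full((n, p), "direct", dtype=object)
    for j, name in enumerate(names):
        grid = stack[name]
        for i, rec in enumerate(sites):
            v = np.nan
            if grid.contains(rec.longitude, rec.latitude):
                v = grid.value_at(rec.longitude, rec.latitude)
            if np.isfinite(v):
                values[i, j] = v
                continue
            found = _nearest_valid(grid, rec.longitude, rec.latitude, max_fallback_km)
            if found is None:
                raise ExtractionError(
                    f"site {rec.id!r}: no valid {name!r} cell within "
                    f"{max_fallback_km} km of ({rec.longitude:.4f}, {rec.latitude:.4f})"
                )
            values[i, j], _ = found
            provenance[i, j] = "nearest-fallback"
    response = np.array([rec.sr_ratio for rec in sites], dtype=float)
    return CovariateMatrix(
        site_ids=[rec.id for rec in sites],
        names=names,
        values=values,
        provenance=provenance,
        response=response,
        lon=np.array([r.longitude for r in sites]),
        lat=np.array([r.latitude for r in sites]),
    )


@dataclasses.dataclass
class PruneReport:
    retained: list[str]
    dropped: list[dict]  # {"dropped", "partner", "r"} per removal

    def as_dict(self) -> dict:
        return {"retained": self.retained, "dropped": self.dropped}


def prune_correlated(frame: pd.DataFrame, threshold: float = 0.9) -> PruneReport:
    """Iteratively remove one member of every |Pearson R| > threshold pair.

    Zero-variance columns are dropped first with their own diagnostic.  Of a
    correlated pair, the member with the larger mean absolute correlation
    against all remaining predictors is dropped; ties fall to the later
    column.  The surviving set has max pairwise |R| <= threshold (asserted).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if frame.shape[1] < 2:
        raise ValueError("need at least two predictors to prune")
    dropped: list[dict] = []
    cols = list(frame.columns)
    sd = frame.std(ddof=0)
    for c in cols[:]:
        if sd[c] == 0 or not np.isfinite(sd[c]):
            cols.remove(c)
            dropped.append({"dropped": c, "partner": None, "r": None,
                            "reason": "zero variance"})
    while len(cols) >= 2:
        corr = frame[cols].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        r = corr[i, j]
        if r <= threshold:
            break
        mean_i = corr[i].sum() / (len(cols) - 1)
        mean_j = corr[j].sum() / (len(cols) - 1)
        if mean_i > mean_j:
            out, partner = i, j
        elif mean_j > mean_i:
            out, partner = j, i
        else:  # tie: drop the later column
            out, partner = (j, i) if j > i else (i, j)
        dropped.append({"dropped": cols[out], "partner": cols[partner], "r": float(r)})
        cols.pop(out)
    if len(cols) >= 2:
        final = frame[cols].corr().abs().to_numpy()
        np.fill_diagonal(final, 0.0)
        assert final.max() <= threshold + 1e-12
    return PruneReport(retained=cols, dropped=dropped)
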