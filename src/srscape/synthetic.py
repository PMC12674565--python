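"""Synthetic landscapes with the statistical structure of a bioavailable
87Sr/86Sr mapping campaign.

The generator builds a piecewise geology (a Voronoi tessellation of units
whose formation age drives the true ratio through an affine-in-log10(age)
link), smooth autocorrelated climate fields, a true isoscape raster, and a
spatially clustered sampling campaign (dense inside one "province" disc,
sparse elsewhere) with additive local and measurement noise.  Everything is
deterministic under the configured seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .grids import RasterGrid, haversine_km
from .samples import SampleRecord

KM_PER_DEG_LAT = 111.19492664455873  # spherical mean


@dataclasses.dataclass
class SimConfig:
    """Study conditions for a synthetic world.

    Sizes are in grid cells / km; ratio terms are in 87Sr/86Sr units.
    """

    width: int = 120
    height: int = 100
    cell_km: float = 1.0
    n_geology_units: int = 12
    age_range_myr: tuple[float, float] = (10.0, 3000.0)
    n_climate_fields: int = 3
    autocorr_km: float = 20.0
    intercept: float = 0.704
    age_slope: float = 0.004          # per log10(Myr)
    climate_slopes: tuple[float, ...] = (0.0008, 0.0005, 0.0003)
    local_noise_sd: float = 0.001
    measurement_noise_sd: float = 1e-4
    n_sites: int = 500
    clustering_fraction: float = 0.5
    cluster_radius_km: float = 30.0
    origin_lon: float = 99.0
    origin_lat: float = 48.5
    seed: int = 0

    def validate(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValueError("grid must be at least 2x2 cells")
        if min(self.local_noise_sd, self.measurement_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.n_geology_units < 1:
            raise ValueError("need at least one geology unit")
        if not (0.0 <= self.clustering_fraction <= 1.0):
            raise ValueError("clustering fraction must be in [0, 1]")
        if self.age_range_myr[0] <= 0 or self.age_range_myr[1] < self.age_range_myr[0]:
            raise ValueError("age range must be positive and ordered")


@dataclasses.dataclass
class SyntheticWorld:
    covariates: dict[str, RasterGrid]
    truth: RasterGrid
    unit_labels: RasterGrid
    unit_ages_myr: np.ndarray
    samples: list[SampleRecord]
    config: SimConfig


def _base_grid(cfg: SimConfig) -> RasterGrid:
    dlat = cfg.cell_km / KM_PER_DEG_LAT
    dlon = cfg.cell_km / (KM_PER_DEG_LAT * np.cos(np.radians(cfg.origin_lat)))
    values = np.zeros((cfg.height, cfg.width))
    return RasterGrid(values, cfg.origin_lon, cfg.origin_lat, dlon, -dlat)


def _gaussian_field(shape: tuple[int, int], length_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth unit-variance field via Gaussian filtering of white noise."""
    white = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(white, sigma=max(length_cells, 1e-6), mode="reflect")
    sd = field.std()
    if sd > 0:
        field = (field - field.mean()) / sd
    return field


def generate_world(config: SimConfig) -> SyntheticWorld:
    """Build covariate rasters, the true isoscape, and a sampling campaign."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = _base_grid(config)
    ny, nx = grid.shape

    # Voronoi geology: nearest of uniformly placed unit seeds (cell units,
    # isotropic because cells are ~square in km)
    seeds_y = rng.uniform(0, ny, config.n_geology_units)
    seeds_x = rng.uniform(0, nx, config.n_geology_units)
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (yy[..., None] - seeds_y) ** 2 + (xx[..., None] - seeds_x) ** 2
    labels = np.argmin(d2, axis=-1)

    lo, hi = config.age_range_myr
    ages = 10 ** rng.uniform(np.log10(lo), np.log10(hi), config.n_geology_units)
    age_raster = ages[labels]

    truth = config.intercept + config.age_slope * np.log10(age_raster)

    covs: dict[str, RasterGrid] = {"age_myr": grid.like(age_raster)}
    slopes = list(config.climate_slopes)
    length_cells = config.autocorr_km / config.cell_km
    for k in range(config.n_climate_fields):
        field = _gaussian_field((ny, nx), length_cells, rng)
        slope = slopes[k] if k < len(slopes) else 0.0
        truth = truth + slope * field
        covs[f"clim_{k}"] = grid.like(field)

    lo_ok, hi_ok = 0.702, 0.760
    if not (truth.min() > lo_ok and truth.max() < hi_ok):
        raise ValueError(
            f"configured response coefficients give implausible ratios "
            f"[{truth.min():.4f}, {truth.max():.4f}] outside ({lo_ok}, {hi_ok})"
        )

    world = SyntheticWorld(
        covariates=covs,
        truth=grid.like(truth),
        unit_labels=grid.like(labels.astype(float)),
        unit_ages_myr=ages,
        samples=[],
        config=config,
    )
    world.samples = sample_sites(world, config.n_sites, config.clustering_fraction,
                                 rng=rng)
    return world


def sample_sites(world: SyntheticWorld, n: int, clustering_fraction: float,
                 seed: int | None = None,
                 rng: np.random.Generator | None = None,
                 cluster_radius_km: float | None = None,
                 cluster_center: tuple[float, float] | None = None) -> list[SampleRecord]:
    """Draw a clustered sampling campaign over the world's grid.

    ``clustering_fraction`` of the sites fall inside one randomly chosen
    disc of radius ``cluster_radius_km`` (the densely surveyed province);
    the rest are uniform over the grid.  Recorded ratio = truth + local
    noise + measurement noise; each record keeps its cell's true ratio.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    cfg = world.config
    radius = cfg.cluster_radius_km if cluster_radius_km is None else cluster_radius_km
    grid = world.truth
    ny, nx = grid.shape
    grid_span_km = max(ny, nx) * cfg.cell_km
    if radius > grid_span_km:
        raise ValueError(f"cluster radius {radius} km exceeds grid span {grid_span_km} km")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    if n == 0:
        return []

    lons, lats = grid.cell_centers()
    lons, lats = lons.ravel(), lats.ravel()

    n_clustered = int(round(clustering_fraction * n))
    chosen: list[int] = []
    if n_clustered > 0:
        if cluster_center is None:
            centre = int(rng.integers(0, lons.size))
            c_lon, c_lat = lons[centre], lats[centre]
        else:
            c_lon, c_lat = cluster_center
        dist = haversine_km(c_lon, c_lat, lons, lats)
        pool = np.flatnonzero(dist <= radius)
        chosen.extend(rng.choice(pool, size=n_clustered, replace=pool.size < n_clustered).tolist())
    n_uniform = n - n_clustered
    if n_uniform > 0:
        chosen.extend(rng.choice(lons.size, size=n_uniform, replace=lons.size < n_uniform).tolist())

    flat_truth = grid.values.ravel()
    local = rng.normal(0.0, cfg.local_noise_sd, size=n) if cfg.local_noise_sd > 0 else np.zeros(n)
    meas = (rng.normal(0.0, cfg.measurement_noise_sd, size=n)
            if cfg.measurement_noise_sd > 0 else np.zeros(n))

    records = []
    for k, cell in enumerate(chosen):
        true = float(flat_truth[cell])
        records.append(SampleRecord(
            id=f"syn{k:04d}",
            longitude=float(lons[cell]),
            latitude=float(lats[cell]),
            material="plant",
            sr_ratio=true + float(local[k]) + float(meas[k]),
            sr_2sigma=2.0 * cfg.measurement_noise_sd,
            source="synthetic",
            true_ratio=true,
        ))
    return records
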