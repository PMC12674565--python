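"""Buffer-based local/non-local assessment of site samples against an
isoscape.

For each site, the range (min, max) of predicted 87Sr/86Sr is extracted
over all valid cells whose centres lie within 10, 20 and 50 km great-circle
radii.  Individual samples are classed as within-range per radius
(closed-interval, boundary counts as local), per-(material, radius)
within-range proportions are reported to two decimals (half-up), and the
site mean's deviation from the nearest range bound is bucketed as inside /
small (< 0.0005) / moderate / large (> 0.001).
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .forest import IsoscapeProduct
from .grids import RasterGrid, haversine_km
from .samples import SiteTable

DEFAULT_RADII_KM = (10.0, 20.0, 50.0)

SMALL_DEVIATION = 0.0005
LARGE_DEVIATION = 0.001

MODERN_PERIODS = {"modern"}


class EmptyRangeError(ValueError):
    """No valid isoscape cell within the requested radius."""


def round2_half_up(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _grid_of(product) -> RasterGrid:
    return product.prediction if isinstance(product, IsoscapeProduct) else product


def local_range(product, lon: float, lat: float, radius_km: float,
                site_id: str = "?") -> tuple[float, float]:
    """Min/max prediction over valid cells with centres within the radius."""
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    grid = _grid_of(product)
    if not grid.contains(lon, lat):
        raise ValueError(f"site {site_id!r} at ({lon}, {lat}) outside raster extent")
    lons, lats = grid.cell_centers()
    within = haversine_km(lon, lat, lons, lats) <= radius_km
    vals = grid.values[within & grid.valid_mask()]
    if vals.size == 0:
        raise EmptyRangeError(f"site {site_id!r}: no valid cell within {radius_km} km")
    return float(vals.min()), float(vals.max())


def _epoch_class(period: str | None) -> str:
    if period is not None and period.strip().lower() in MODERN_PERIODS:
        return "modern"
    return "archaeological"


def pool_site_samples(table: SiteTable) -> pd.DataFrame:
    """Mean ratio per (site, material, epoch class); archaeological and
    modern samples are pooled separately."""
    rows = []
    for site in table.sites.values():
        groups: dict[tuple[str, str], list[float]] = {}
        for s in site.samples:
            groups.setdefault((s.material, _epoch_class(s.period)), []).append(s.sr_ratio)
        for (material, epoch), vals in sorted(groups.items()):
            rows.append({
                "site": site.site_id,
                "material": material,
                "epoch_class": epoch,
                "n": len(vals),
                "mean_ratio": float(np.mean(vals)),
            })
    return pd.DataFrame(rows)


def deviation_from_range(value: float, rng: tuple[float, float]) -> float:
    """0 when inside the closed interval, else distance to the nearest bound."""
    lo, hi = rng
    if lo <= value <= hi:
        return 0.0
    return float(lo - value) if value < lo else float(value - hi)


def deviation_category(dev: float) -> str:
    if dev == 0.0:
        return "inside"
    if dev < SMALL_DEVIATION:
        return "small"
    if dev <= LARGE_DEVIATION:
        return "moderate"
    return "large"


@dataclasses.dataclass
class SiteAssessment:
    """Assessment of one (site, material, epoch-class) group."""

    site: str
    material: str
    epoch_class: str
    coord_provenance: str
    n: int
    ranges: dict[float, tuple[float, float]]      # radius km -> (min, max)
    within_flags: dict[float, list[bool]]         # radius km -> per-sample flags
    proportions: dict[float, float | None]        # radius km -> % within (None if summary-only)
    mean_ratio: float
    mean_within: dict[float, bool]
    deviation: dict[float, float]
    category: str                                  # from the largest radius
    summary_only: bool

    def assert_invariants(self) -> None:
        radii = sorted(self.ranges)
        for a, b in zip(radii, radii[1:]):
            lo_a, hi_a = self.ranges[a]
            lo_b, hi_b = self.ranges[b]
            assert lo_b <= lo_a and hi_a <= hi_b, "ranges must nest with radius"
        props = [self.proportions[r] for r in radii if self.proportions[r] is not None]
        assert all(0.0 <= p <= 100.0 for p in props)
        assert all(p1 <= p2 + 1e-9 for p1, p2 in zip(props, props[1:])), \
            "proportions must be non-decreasing in radius"


def assess_sites(product, table: SiteTable,
                 radii=DEFAULT_RADII_KM) -> list[SiteAssessment]:
    """Assess every (site, material, epoch-class) group against the isoscape."""
    radii = sorted(float(r) for r in radii)
    out: list[SiteAssessment] = []
    for site in table.sites.values():
        ranges = {r: local_range(product, site.longitude, site.latitude, r, site.site_id)
                  for r in radii}
        groups: dict[tuple[str, str], list] = {}
        for s in site.samples:
            groups.setdefault((s.material, _epoch_class(s.period)), []).append(s)
        for (material, epoch), samples in sorted(groups.items()):
            ratios = [s.sr_ratio for s in samples]
            mean = float(np.mean(ratios))
            flags = {r: [ranges[r][0] <= v <= ranges[r][1] for v in ratios] for r in radii}
            if site.summary_only:
                proportions: dict[float, float | None] = {r: None for r in radii}
            else:
                proportions = {r: round2_half_up(100.0 * sum(flags[r]) / len(ratios))
                               for r in radii}
            dev = {r: deviation_from_range(mean, ranges[r]) for r in radii}
            assessment = SiteAssessment(
                site=site.site_id, material=material, epoch_class=epoch,
                coord_provenance=site.coord_provenance,
                n=len(samples), ranges=ranges, within_flags=flags,
                proportions=proportions, mean_ratio=mean,
                mean_within={r: dev[r] == 0.0 for r in radii},
                deviation=dev, category=deviation_category(dev[radii[-1]]),
                summary_only=site.summary_only,
            )
            assessment.assert_invariants()
            out.append(assessment)
    return out


def assessment_table(assessments: list[SiteAssessment],
                     radii=DEFAULT_RADII_KM) -> pd.DataFrame:
    """Flatten assessments into the standard per-site proportion layout."""
    radii = sorted(float(r) for r in radii)
    rows = []
    for a in assessments:
        row = {
            "site": a.site,
            "type": a.material,
            "epoch_class": a.epoch_class,
            "n": a.n,
            "coord_provenance": a.coord_provenance,
            "mean_ratio": a.mean_ratio,
            "deviation_category": a.category,
        }
        for r in radii:
            row[f"pct_within_{r:g}km"] = a.proportions[r]
            row[f"mean_within_{r:g}km"] = a.mean_within[r]
        rows.append(row)
    return pd.DataFrame(rows)
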