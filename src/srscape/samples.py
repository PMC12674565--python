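"""Tabular readers/writers for georeferenced 87Sr/86Sr sample databases.

Two schemas are supported: the bioavailable-database layout (``sm1``: one
measurement per row with site id, coordinates, material and ratio) and the
archaeological site layout (``sm2``: rows grouped by site, carrying period
and a coordinate-provenance flag).  ``synthetic`` is ``sm1`` plus an optional
column with the generating cell's true ratio, used in recovery tests.

Parsers are total: malformed rows are rejected with row-indexed diagnostics,
never silently dropped or partially loaded.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from pathlib import Path

import pandas as pd

RATIO_LO, RATIO_HI = 0.700, 0.760

MATERIALS = {"plant", "soil", "animal", "human"}
# common field synonyms normalised on load
_MATERIAL_SYNONYMS = {
    "rodent": "animal",
    "fauna": "animal",
    "grass": "plant",
    "vegetation": "plant",
}

COORD_PROVENANCE = {"exact", "approximated-from-map", "averaged"}


class SchemaError(ValueError):
    """A mandatory column is missing or the declared schema is unknown."""


@dataclasses.dataclass
class SampleRecord:
    """One georeferenced 87Sr/86Sr measurement."""

    id: str
    longitude: float
    latitude: float
    material: str
    sr_ratio: float
    sr_2sigma: float | None = None
    source: str = ""
    period: str | None = None
    true_ratio: float | None = None  # synthetic ground truth, if known

    def validate(self) -> None:
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not (RATIO_LO < self.sr_ratio < RATIO_HI):
            raise ValueError(f"sr_ratio {self.sr_ratio} outside plausible range ({RATIO_LO}, {RATIO_HI})")
        if self.sr_2sigma is not None and self.sr_2sigma < 0:
            raise ValueError(f"sr_2sigma {self.sr_2sigma} negative")
        if self.material not in MATERIALS:
            raise ValueError(f"material {self.material!r} not one of {sorted(MATERIALS)}")


@dataclasses.dataclass
class Site:
    """A sampling/archaeological site with its pooled measurements."""

    site_id: str
    longitude: float
    latitude: float
    coord_provenance: str = "exact"
    samples: list[SampleRecord] = dataclasses.field(default_factory=list)
    summary_only: bool = False  # per-site summary rows, no individual values


@dataclasses.dataclass
class SiteTable:
    sites: "OrderedDict[str, Site]"
    rejected: list[tuple[int, str]] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def all_samples(self) -> list[SampleRecord]:
        return [s for site in self.sites.values() for s in site.samples]


@dataclasses.dataclass
class ParsedSamples:
    records: list[SampleRecord]
    rejected: list[tuple[int, str]]


_SM1_REQUIRED = ["site_id", "longitude", "latitude", "material", "sr_ratio"]
_SM2_REQUIRED = ["site", "longitude", "latitude", "material", "period", "sr_ratio"]


def _load_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path)
    return pd.read_csv(path)


def _normalise_material(value: object) -> str:
    m = str(value).strip().lower()
    return _MATERIAL_SYNONYMS.get(m, m)


def _row_record(row: pd.Series, idx: int, id_col: str) -> SampleRecord:
    ratio = float(row["sr_ratio"])
    two_sigma = row.get("sr_2sigma")
    two_sigma = None if two_sigma is None or pd.isna(two_sigma) else float(two_sigma)
    period = row.get("period")
    period = None if period is None or pd.isna(period) else str(period)
    rec = SampleRecord(
        id=str(row[id_col]),
        longitude=float(row["longitude"]),
        latitude=float(row["latitude"]),
        material=_normalise_material(row["material"]),
        sr_ratio=ratio,
        sr_2sigma=two_sigma,
        source=str(row.get("source", "") or ""),
        period=period,
        true_ratio=None if pd.isna(row.get("true_ratio")) else float(row["true_ratio"]),
    )
    rec.validate()
    return rec


def read_sample_table(path: str | Path, schema: str = "sm1"):
    """Parse a sample table.

    Returns :class:`ParsedSamples` for ``sm1``/``synthetic`` and a
    :class:`SiteTable` for ``sm2``.  Rows violating record invariants are
    collected in ``rejected`` as ``(row_index, reason)``; a missing mandatory
    column raises :class:`SchemaError` naming it.
    """
    schema = schema.lower()
    if schema not in {"sm1", "sm2", "synthetic"}:
        raise SchemaError(f"unknown schema {schema!r}; expected sm1, sm2 or synthetic")
    frame = _load_frame(path)
    frame.columns = [str(c).strip().lower() for c in frame.columns]

    required = _SM2_REQUIRED if schema == "sm2" else _SM1_REQUIRED
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r} for schema {schema}")

    if schema in {"sm1", "synthetic"}:
        records: list[SampleRecord] = []
        rejected: list[tuple[int, str]] = []
        for idx, row in frame.iterrows():
            try:
                records.append(_row_record(row, idx, "site_id"))
            except (ValueError, TypeError) as exc:
                rejected.append((int(idx), str(exc)))
        return ParsedSamples(records, rejected)

    sites: OrderedDict[str, Site] = OrderedDict()
    rejected = []
    for idx, row in frame.iterrows():
        try:
            rec = _row_record(row, idx, "site")
            prov = str(row.get("coord_provenance", "") or "exact").strip().lower()
            if prov not in COORD_PROVENANCE:
                prov = "exact"
            summary = bool(row.get("summary_only", False)) and not pd.isna(row.get("summary_only"))
        except (ValueError, TypeError) as exc:
            rejected.append((int(idx), str(exc)))
            continue
        site = sites.get(rec.id)
        if site is None:
            site = Site(rec.id, rec.longitude, rec.latitude, prov)
            sites[rec.id] = site
        site.samples.append(rec)
        site.summary_only = site.summary_only or summary
    return SiteTable(sites, rejected)


def write_sample_table(records: list[SampleRecord], path: str | Path,
                       include_truth: bool = False) -> Path:
    """Write records as CSV in the sm1 column layout."""
    rows = []
    for r in records:
        row = {
            "site_id": r.id,
            "longitude": r.longitude,
            "latitude": r.latitude,
            "material": r.material,
            "sr_ratio": r.sr_ratio,
            "sr_2sigma": r.sr_2sigma,
            "source": r.source,
        }
        if include_truth:
            row["true_ratio"] = r.true_ratio
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
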