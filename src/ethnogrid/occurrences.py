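"""Georeferenced occurrence records: loading, cleaning, trait enrichment.

Occurrences are specimen or observation records (herbarium + aggregator
exports) with WGS84 decimal-degree coordinates.  Cleaning never hard-fails:
each input row is either accepted (with a canonicalized species name) or
rejected with a logged reason, so accepted + rejected always equals the
input count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import ValidationError
from .trait_db import TraitDB, canonicalize_name

logger = logging.getLogger(__name__)

#: Default column mapping for occurrence CSVs (Darwin-Core-like names).
DEFAULT_OCCURRENCE_COLUMNS: dict[str, str] = {
    "record_id": "occurrenceID",
    "species_name": "scientificName",
    "longitude": "decimalLongitude",
    "latitude": "decimalLatitude",
    "year": "year",
    "source": "institutionCode",
    "municipality": "municipality",
    "voucher": "catalogNumber",
}


@dataclass(frozen=True)
class OccurrenceRecord:
    """One cleaned georeferenced record of a medicinal species."""

    record_id: str
    species_name_raw: str
    species_name: str
    longitude: float
    latitude: float
    year: int | None = None
    source: str | None = None
    municipality: str | None = None
    voucher: str | None = None


@dataclass(frozen=True)
class EnrichedOccurrence(OccurrenceRecord):
    """An occurrence carrying the disease-class set of its species."""

    disease_classes: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.disease_classes:
            raise ValidationError(
                f"{self.species_name}: enriched occurrence with empty class set"
            )

    @property
    def n_classes(self) -> int:
        return len(self.disease_classes)


def load_occurrences(
    path, column_map: dict[str, str] | None = None, sep: str | None = None
) -> list[dict]:
    """Read raw occurrence rows, preserving file order.

    Rows are returned as field -> string dicts using the package's internal
    field names.  Rows without an id get a stable synthetic ``record_id``
    (1-based row index).  No cleaning happens here; rows with empty or
    malformed coordinates are retained for the cleaning stage.
    """
    from .trait_db import _read_delimited  # same dialect handling

    columns = dict(DEFAULT_OCCURRENCE_COLUMNS)
    if column_map:
        columns.update(column_map)
    df = _read_delimited(path, sep=sep)
    for fld in ("species_name", "longitude", "latitude"):
        if columns[fld] not in df.columns:
            raise ValidationError(f"missing required column {columns[fld]!r}")
    rows = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        out = {}
        for fld, col in columns.items():
            val = str(row[col]).strip() if col in df.columns else ""
            out[fld] = val
        if not out.get("record_id"):
            out["record_id"] = str(i)
        rows.append(out)
    return rows


@dataclass(frozen=True)
class Rejection:
    record_id: str
    species_name_raw: str
    reason: str


def _raw_fields(row) -> dict:
    """Accept raw dict rows (internal or Darwin-Core-named keys) and
    already-built OccurrenceRecord objects."""
    if isinstance(row, dict):
        if "species_name" not in row and "scientificName" in row:
            row = {
                fld: row.get(col, "") for fld, col in DEFAULT_OCCURRENCE_COLUMNS.items()
            }
        return row
    if isinstance(row, OccurrenceRecord):
        return {
            "record_id": row.record_id,
            "species_name": row.species_name,
            "species_name_raw": row.species_name_raw,
            "longitude": row.longitude,
            "latitude": row.latitude,
            "year": "" if row.year is None else row.year,
            "source": row.source or "",
            "municipality": row.municipality or "",
            "voucher": row.voucher or "",
        }
    return row


def clean_occurrences(
    rows: Iterable,
    db: TraitDB,
    bbox: tuple[float, float, float, float] | None = None,
    dedupe: bool = False,
    min_year: int | None = None,
    strip_authors: bool = True,
) -> tuple[list[OccurrenceRecord], list[Rejection]]:
    """Filter raw rows into valid occurrence records plus a rejection log.

    Rejection rules: missing/unparseable coordinates; coordinates outside
    the valid lon/lat ranges; exact (0, 0) coordinates (a common aggregator
    placeholder, treated as missing); outside ``bbox`` when one is given
    (west, south, east, north); species absent from the trait catalogue
    after canonicalization; duplicates of (species, lon, lat) when
    ``dedupe``; collection year before ``min_year`` when set.

    Cleaning is idempotent: re-cleaning accepted records changes nothing.
    """
    accepted: list[OccurrenceRecord] = []
    rejected: list[Rejection] = []
    seen: set[tuple[str, float, float]] = set()
    for row in rows:
        raw = _raw_fields(row)
        rid = str(raw.get("record_id", ""))
        raw_name = str(raw.get("species_name", "")).strip()
        orig_name = str(raw.get("species_name_raw", "")).strip() or raw_name

        def reject(reason: str):
            rejected.append(Rejection(rid, orig_name, reason))
            logger.warning("record %s rejected: %s", rid, reason)

        if not raw_name:
            reject("missing species name")
            continue
        lon_raw, lat_raw = raw.get("longitude", ""), raw.get("latitude", "")
        if str(lon_raw).strip() == "" or str(lat_raw).strip() == "":
            reject("missing coordinates")
            continue
        try:
            lon, lat = float(lon_raw), float(lat_raw)
        except (TypeError, ValueError):
            reject("unparseable coordinates")
            continue
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            reject("coordinate out of range")
            continue
        if lon == 0.0 and lat == 0.0:
            reject("zero-zero coordinates")
            continue
        if bbox is not None:
            west, south, east, north = bbox
            if not (west <= lon <= east and south <= lat <= north):
                reject("outside bounding box")
                continue
        name = canonicalize_name(raw_name, strip_authors=strip_authors)
        if name not in db:
            reject("no trait record")
            continue
        year_raw = str(raw.get("year", "")).strip()
        year: int | None = None
        if year_raw:
            try:
                year = int(float(year_raw))
            except ValueError:
                year = None  # year is optional metadata; keep the record
        if min_year is not None and year is not None and year < min_year:
            reject("before minimum year")
            continue
        if dedupe:
            key = (name, lon, lat)
            if key in seen:
                reject("duplicate record")
                continue
            seen.add(key)
        accepted.append(
            OccurrenceRecord(
                record_id=rid,
                species_name_raw=orig_name,
                species_name=name,
                longitude=lon,
                latitude=lat,
                year=year,
                source=str(raw.get("source", "")).strip() or None,
                municipality=str(raw.get("municipality", "")).strip() or None,
                voucher=str(raw.get("voucher", "")).strip() or None,
            )
        )
    return accepted, rejected


def join_traits(
    records: Iterable[OccurrenceRecord], db: TraitDB
) -> list[EnrichedOccurrence]:
    """Attach each species' disease-class set to its occurrence records.

    Order and count are preserved.  A species missing from the catalogue is
    a hard error here — it means the cleaning stage was skipped.
    """
    out = []
    for rec in records:
        if rec.species_name not in db:
            raise LookupError(
                f"species {rec.species_name!r} has no trait record; "
                "run clean_occurrences first"
            )
        out.append(
            EnrichedOccurrence(
                **{k: getattr(rec, k) for k in (
                    "record_id", "species_name_raw", "species_name",
                    "longitude", "latitude", "year", "source",
                    "municipality", "voucher",
                )},
                disease_classes=db[rec.species_name].disease_classes,
            )
        )
    return out


def rejections_to_dataframe(rejections: list[Rejection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"record_id": r.record_id, "species_name_raw": r.species_name_raw,
             "reason": r.reason}
            for r in rejections
        ],
        columns=["record_id", "species_name_raw", "reason"],
    )
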