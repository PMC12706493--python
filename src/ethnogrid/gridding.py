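"""Equal-angle gridding and the ethnomedicinal index (EI).

Occurrences are binned into square cells of `cell_size` decimal degrees
(default 0.045 dd, roughly 5 km across at these latitudes).  Per cell we
report species richness SR (unique species), disease-class coverage (size
of the union of member species' class sets), and the ethnomedicinal index

    EI = sum_i n_i / N

where n_i is the number of disease classes treated by the i-th *unique*
species present in the cell and N is the total number of classes in the
scheme (19 by default).  Record multiplicity affects only record_count:
the index sums over species, not specimens.

Cell membership is half-open: a point on a shared edge belongs to the cell
whose west/south edge it sits on, so cells partition the plane with no
double counting.  The grid anchor (origin) defaults to (0, 0), i.e. cell
edges at integer multiples of cell_size; it is configurable because
published per-cell counts depend on the (often unstated) anchor used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError
from .occurrences import EnrichedOccurrence
from .trait_db import N_CLASSES

CellIndex = tuple[int, int]  # (i, j) = (column, row)


@dataclass(frozen=True)
class GridSpec:
    """Equal-angle grid definition (WGS84 decimal degrees)."""

    cell_size: float = 0.045
    origin_lon: float = 0.0
    origin_lat: float = 0.0

    def __post_init__(self):
        if not (self.cell_size > 0):
            raise ValidationError(f"cell_size must be > 0, got {self.cell_size}")


def cell_of(longitude: float, latitude: float, spec: GridSpec = GridSpec()) -> CellIndex:
    """Cell index of a point: floor((coord - origin) / cell_size) per axis."""
    i = math.floor((longitude - spec.origin_lon) / spec.cell_size)
    j = math.floor((latitude - spec.origin_lat) / spec.cell_size)
    return (i, j)


def cell_bounds(index: CellIndex, spec: GridSpec = GridSpec()) -> tuple[float, float, float, float]:
    """(west, south, east, north) of a cell; half-open on east/north."""
    i, j = index
    west = spec.origin_lon + i * spec.cell_size
    south = spec.origin_lat + j * spec.cell_size
    return (west, south, west + spec.cell_size, south + spec.cell_size)


def ethnomedicinal_index(class_counts: Iterable[int], n_classes_total: int = N_CLASSES) -> float:
    """EI = sum of per-species class counts n_i divided by N.

    ``class_counts`` holds one n_i per unique species in the spatial unit;
    an empty list gives 0.  Each n_i must lie in [1, N].
    """
    if n_classes_total < 1:
        raise ValidationError(f"N must be >= 1, got {n_classes_total}")
    counts = list(class_counts)
    bad = [c for c in counts if not (1 <= c <= n_classes_total)]
    if bad:
        raise ValidationError(
            f"per-species class counts outside [1, {n_classes_total}]: {bad}"
        )
    return sum(counts) / n_classes_total


@dataclass
class CellSummary:
    """Aggregate view of one occupied grid cell."""

    index: CellIndex
    bounds: tuple[float, float, float, float]
    species: frozenset[str]
    record_count: int
    richness: int
    class_union: frozenset[str]
    class_coverage: int
    ei: float


def aggregate_cells(
    records: Iterable[EnrichedOccurrence],
    spec: GridSpec = GridSpec(),
    n_classes_total: int = N_CLASSES,
) -> dict[CellIndex, CellSummary]:
    """Bin enriched occurrences into cells and summarize each occupied cell.

    A species contributes once to a cell's species set regardless of how
    many records fall there; class coverage is the union over member
    species; EI sums unique-species n_i values.  Cells with no records are
    not emitted, so every returned cell has richness >= 1.
    """
    species_classes: dict[CellIndex, dict[str, frozenset[str]]] = {}
    counts: dict[CellIndex, int] = {}
    for rec in records:
        idx = cell_of(rec.longitude, rec.latitude, spec)
        cell = species_classes.setdefault(idx, {})
        cell[rec.species_name] = rec.disease_classes
        counts[idx] = counts.get(idx, 0) + 1
    out: dict[CellIndex, CellSummary] = {}
    for idx, members in species_classes.items():
        union: set[str] = set()
        for classes in members.values():
            union |= classes
        out[idx] = CellSummary(
            index=idx,
            bounds=cell_bounds(idx, spec),
            species=frozenset(members),
            record_count=counts[idx],
            richness=len(members),
            class_union=frozenset(union),
            class_coverage=len(union),
            ei=ethnomedicinal_index(
                [len(c) for c in members.values()], n_classes_total
            ),
        )
    return out


# --- export -----------------------------------------------------------------


def _sorted_cells(cells: Mapping[CellIndex, CellSummary]) -> list[CellSummary]:
    return [cells[k] for k in sorted(cells, key=lambda ij: (ij[1], ij[0]))]


def cells_to_dataframe(cells: Mapping[CellIndex, CellSummary]) -> pd.DataFrame:
    """Flat per-cell table, sorted south-to-north then west-to-east."""
    rows = []
    for c in _sorted_cells(cells):
        west, south, east, north = c.bounds
        rows.append(
            {
                "i": c.index[0], "j": c.index[1],
                "west": west, "south": south, "east": east, "north": north,
                "richness": c.richness, "record_count": c.record_count,
                "class_coverage": c.class_coverage, "ei": c.ei,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["i", "j", "west", "south", "east", "north",
                 "richness", "record_count", "class_coverage", "ei"],
    )


def cells_to_geojson(cells: Mapping[CellIndex, CellSummary]) -> dict:
    """GeoJSON FeatureCollection: one closed counter-clockwise Polygon per cell."""
    features = []
    for c in _sorted_cells(cells):
        west, south, east, north = c.bounds
        ring = [
            [west, south], [east, south], [east, north], [west, north],
            [west, south],
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "i": c.index[0], "j": c.index[1],
                    "richness": c.richness,
                    "record_count": c.record_count,
                    "class_coverage": c.class_coverage,
                    "ei": c.ei,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
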