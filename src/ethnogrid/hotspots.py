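"""Hotspot ranking and municipality-level aggregation.

A hotspot is a grid cell (or administrative unit) with an exceptionally
high ethnomedicinal index, species richness, or disease-class coverage —
a candidate priority area for bioprospecting and conservation.  Ranking is
fully deterministic: metric descending, ties broken by (row, column)
ascending, so repeated runs and permuted inputs give identical reports.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from shapely.geometry import Point, shape

from .errors import ValidationError
from .gridding import CellIndex, CellSummary
from .occurrences import EnrichedOccurrence

logger = logging.getLogger(__name__)

METRICS = ("richness", "class_coverage", "ei")


@dataclass
class HotspotReport:
    """Ranked cells plus the subset selected as hotspots under a stated rule."""

    metric: str
    ranked_cells: list[tuple[CellIndex, float]]
    selection: list[tuple[CellIndex, float]]
    rule: dict

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "rule": self.rule,
            "ranked_cells": [
                {"i": ij[0], "j": ij[1], "value": v} for ij, v in self.ranked_cells
            ],
            "selection": [
                {"i": ij[0], "j": ij[1], "value": v} for ij, v in self.selection
            ],
        }

    def to_dataframe(self) -> pd.DataFrame:
        sel = {ij for ij, _ in self.selection}
        return pd.DataFrame(
            [
                {"rank": r, "i": ij[0], "j": ij[1], "metric": self.metric,
                 "value": v, "hotspot": ij in sel}
                for r, (ij, v) in enumerate(self.ranked_cells, start=1)
            ],
            columns=["rank", "i", "j", "metric", "value", "hotspot"],
        )


def rank_cells(
    cells: Mapping[CellIndex, CellSummary], metric: str = "ei"
) -> list[tuple[CellIndex, float]]:
    """Total deterministic order over cells: metric desc, then (j, i) asc."""
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if not cells:
        raise ValidationError("cannot rank an empty cell map")
    keyed = [
        (idx, float(getattr(summary, metric))) for idx, summary in cells.items()
    ]
    keyed.sort(key=lambda kv: (-kv[1], kv[0][1], kv[0][0]))
    return keyed


def select_hotspots(
    ranked: list[tuple[CellIndex, float]],
    metric: str = "ei",
    k: int | None = None,
    threshold: float | None = None,
) -> HotspotReport:
    """Flag hotspots from a ranked list by top-k or metric >= threshold.

    Exactly one of ``k`` / ``threshold`` must be given.  An empty selection
    (threshold above the maximum) is valid and logged as a warning.
    """
    if (k is None) == (threshold is None):
        raise ValidationError("give exactly one of k or threshold")
    if k is not None:
        if k <= 0:
            raise ValidationError(f"k must be positive, got {k}")
        selection = ranked[:k]
        rule = {"type": "top_k", "k": k}
    else:
        if not math.isfinite(threshold):
            raise ValidationError(f"threshold must be finite, got {threshold}")
        selection = [(ij, v) for ij, v in ranked if v >= threshold]
        rule = {"type": "threshold", "threshold": threshold}
    if not selection:
        logger.warning("hotspot rule %s selected no cells", rule)
    return HotspotReport(metric=metric, ranked_cells=list(ranked),
                         selection=selection, rule=rule)


# --- municipality aggregation ----------------------------------------------


def _load_boundaries(boundary_source) -> list[tuple[str, object]]:
    """Read (name, shapely geometry) pairs from GeoJSON, keeping file order."""
    if isinstance(boundary_source, (str, Path)):
        with open(boundary_source) as fh:
            gj = json.load(fh)
    else:
        gj = boundary_source
    feats = gj.get("features", [])
    out = []
    for k, feat in enumerate(feats):
        name = str(feat.get("properties", {}).get("name", f"polygon-{k + 1}"))
        out.append((name, shape(feat["geometry"])))
    return out


def municipality_summary(
    records: Iterable[EnrichedOccurrence],
    boundary_source=None,
) -> pd.DataFrame:
    """Per-municipality species richness, class coverage, and record count.

    Municipality comes from the record attribute, or — when
    ``boundary_source`` (GeoJSON polygons with a "name" property, WGS84
    lon/lat) is given — from point-in-polygon lookup, with points on a
    shared boundary assigned to the first matching polygon in file order.
    Unresolvable records are tallied under "unassigned".  A species
    occurring in two municipalities counts in both; there is no global
    dedup across units.
    """
    boundaries = _load_boundaries(boundary_source) if boundary_source else None
    species: dict[str, set[str]] = {}
    classes: dict[str, set[str]] = {}
    n_records: dict[str, int] = {}
    for rec in records:
        unit = None
        if boundaries is not None:
            pt = Point(rec.longitude, rec.latitude)
            for name, geom in boundaries:
                if geom.covers(pt):
                    unit = name
                    break
        else:
            unit = rec.municipality
        unit = unit or "unassigned"
        species.setdefault(unit, set()).add(rec.species_name)
        classes.setdefault(unit, set()).update(rec.disease_classes)
        n_records[unit] = n_records.get(unit, 0) + 1
    rows = [
        {
            "municipality": unit,
            "richness": len(species[unit]),
            "class_coverage": len(classes[unit]),
            "record_count": n_records[unit],
        }
        for unit in species
    ]
    rows.sort(key=lambda r: (-r["richness"], r["municipality"]))
    return pd.DataFrame(
        rows, columns=["municipality", "richness", "class_coverage", "record_count"]
    )
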