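"""End-to-end pipeline: catalogue + occurrences -> map layers and reports.

Replicates the full mapping workflow in one call: load and validate the
trait catalogue, load/clean/enrich occurrences, bin into the equal-angle
grid, compute per-cell richness / class coverage / EI, rank hotspots, and
write the artifact bundle (GeoJSON + CSV cell layers, hotspot report,
summary report, rejection log, provenance record).  All files are written
atomically (temp file + rename) and all numeric artifacts carry full
precision; display rounding happens only in the plain-text report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, EthnogridError
from .gridding import (
    GridSpec,
    aggregate_cells,
    cells_to_dataframe,
    cells_to_geojson,
)
from .hotspots import municipality_summary, rank_cells, select_hotspots
from .occurrences import (
    clean_occurrences,
    join_traits,
    load_occurrences,
    rejections_to_dataframe,
)
from .trait_db import (
    N_CLASSES,
    class_count_distribution,
    disease_class_table,
    load_trait_db,
    summarize_categorical,
    summarize_taxonomy,
)

logger = logging.getLogger(__name__)

_CATEGORICAL_FIELDS = (
    "origin", "endemic", "habitats", "growth_forms", "parts_used",
    "iucn_category", "nom059_category",
)


@dataclass
class PipelineConfig:
    """Everything one mapping run needs; loadable from a YAML file."""

    trait_path: str
    occurrence_path: str
    out_dir: str
    boundaries_path: str | None = None
    trait_columns: dict | None = None
    occurrence_columns: dict | None = None
    multi_delimiter: str = ";"
    cell_size: float = 0.045
    grid_origin: tuple[float, float] = (0.0, 0.0)
    derive_n: bool = False
    bbox: tuple[float, float, float, float] | None = None
    dedupe: bool = False
    min_year: int | None = None
    hotspot_metric: str = "ei"
    hotspot_threshold: float | None = 15.0
    hotspot_k: int | None = None
    log_level: str = "INFO"
    render: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.bbox is not None:
            cfg.bbox = tuple(cfg.bbox)
        cfg.grid_origin = tuple(cfg.grid_origin)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_origin"] = list(self.grid_origin)
        if self.bbox is not None:
            d["bbox"] = list(self.bbox)
        return d


@dataclass
class PipelineResult:
    """In-memory view of a finished run plus the paths of its artifacts."""

    cells: dict
    hotspot_report: object
    summary: dict
    rejections: object
    municipality_table: object
    artifact_paths: dict[str, Path] = field(default_factory=dict)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _json_dumps(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True) + "\n"


def _text_report(summary: dict) -> str:
    """Aligned plain-text rendering of the summary (1-decimal EI display)."""
    lines = []
    tax = summary["taxonomy"]
    lines.append("Catalogue")
    lines.append(f"  species   {tax['n_species']:>6}")
    lines.append(f"  families  {tax['n_families']:>6}")
    lines.append(f"  genera    {tax['n_genera']:>6}")
    dist = summary["class_count_distribution"]
    lines.append("Disease classes per species (n_i)")
    lines.append(f"  n_i = 1        {dist['n_1']:>6}")
    lines.append(f"  n_i = 2        {dist['n_2']:>6}")
    lines.append(f"  n_i >= 3       {dist['n_3_or_more']:>6}")
    for fld, tally in summary["categorical"].items():
        lines.append(f"{fld}")
        for value, count in tally.items():
            lines.append(f"  {value:<22} {count:>6}")
    occ = summary["occurrence_counts"]
    lines.append("Occurrences")
    lines.append(f"  input rows       {occ['n_input_rows']:>7}")
    lines.append(f"  accepted         {occ['n_accepted']:>7}")
    lines.append(f"  rejected         {occ['n_rejected']:>7}")
    lines.append(f"  species observed {occ['n_species_observed']:>7}")
    lines.append(f"  occupied cells   {occ['n_cells']:>7}")
    grid = summary["grid"]
    lines.append("Grid maxima")
    lines.append(f"  max richness        {grid['max_richness']:>7}")
    lines.append(f"  max class coverage  {grid['max_class_coverage']:>7}")
    lines.append(f"  max EI              {grid['max_ei']:>9.1f}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the artifact bundle to ``out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except FileNotFoundError as exc:
            raise EthnogridError(f"stage {name}: missing input file {exc.filename}") from exc
        except EthnogridError as exc:
            raise EthnogridError(f"stage {name}: {exc}") from exc

    db = stage(
        "load_trait_db", load_trait_db, config.trait_path,
        column_map=config.trait_columns, multi_delimiter=config.multi_delimiter,
    )
    raw_rows = stage(
        "load_occurrences", load_occurrences, config.occurrence_path,
        column_map=config.occurrence_columns,
    )
    accepted, rejected = stage(
        "clean_occurrences", clean_occurrences, raw_rows, db,
        bbox=config.bbox, dedupe=config.dedupe, min_year=config.min_year,
    )
    enriched = stage("join_traits", join_traits, accepted, db)
    n_total = db.derived_n_classes() if config.derive_n else N_CLASSES
    spec = GridSpec(
        cell_size=config.cell_size,
        origin_lon=config.grid_origin[0],
        origin_lat=config.grid_origin[1],
    )
    cells = stage("aggregate_cells", aggregate_cells, enriched, spec, n_total)
    ranked = stage("rank_cells", rank_cells, cells, config.hotspot_metric)
    report = stage(
        "select_hotspots", select_hotspots, ranked, metric=config.hotspot_metric,
        k=config.hotspot_k,
        threshold=config.hotspot_threshold if config.hotspot_k is None else None,
    )
    muni_table = stage(
        "municipality_summary", municipality_summary, enriched,
        boundary_source=config.boundaries_path,
    )

    table = disease_class_table(db)
    summary = {
        "taxonomy": summarize_taxonomy(db),
        "categorical": {
            f: summarize_categorical(db, f) for f in _CATEGORICAL_FIELDS
        },
        "class_count_distribution": class_count_distribution(db),
        "disease_class_table": [
            {k: (None if pd.isna(v) else v) for k, v in row.items()}
            for row in table.to_dict(orient="records")
        ],
        "occurrence_counts": {
            "n_input_rows": len(raw_rows),
            "n_accepted": len(accepted),
            "n_rejected": len(rejected),
            "n_species_observed": len({r.species_name for r in accepted}),
            "n_cells": len(cells),
        },
        "grid": {
            "cell_size": spec.cell_size,
            "origin": [spec.origin_lon, spec.origin_lat],
            "n_classes_total": n_total,
            "max_richness": max((c.richness for c in cells.values()), default=0),
            "max_class_coverage": max(
                (c.class_coverage for c in cells.values()), default=0
            ),
            "max_ei": max((c.ei for c in cells.values()), default=0.0),
        },
    }

    paths = {
        "cell_layer_geojson": out_dir / "cells.geojson",
        "cell_layer_csv": out_dir / "cells.csv",
        "hotspots_json": out_dir / "hotspots.json",
        "hotspots_csv": out_dir / "hotspots.csv",
        "summary_json": out_dir / "summary.json",
        "summary_txt": out_dir / "summary.txt",
        "disease_class_table_csv": out_dir / "disease_class_table.csv",
        "municipality_csv": out_dir / "municipalities.csv",
        "rejections_csv": out_dir / "rejections.csv",
        "provenance_json": out_dir / "provenance.json",
    }
    _atomic_write_text(paths["cell_layer_geojson"], _json_dumps(cells_to_geojson(cells)))
    _atomic_write_text(paths["cell_layer_csv"], cells_to_dataframe(cells).to_csv(index=False))
    _atomic_write_text(paths["hotspots_json"], _json_dumps(report.to_dict()))
    _atomic_write_text(paths["hotspots_csv"], report.to_dataframe().to_csv(index=False))
    _atomic_write_text(paths["summary_json"], _json_dumps(summary))
    _atomic_write_text(paths["summary_txt"], _text_report(summary))
    _atomic_write_text(paths["disease_class_table_csv"], table.to_csv(index=False))
    _atomic_write_text(paths["municipality_csv"], muni_table.to_csv(index=False))
    _atomic_write_text(
        paths["rejections_csv"], rejections_to_dataframe(rejected).to_csv(index=False)
    )
    provenance = {
        "package": "ethnogrid",
        "version": __version__,
        "config": config.to_dict(),
        "input_checksums": {
            "trait_csv": _sha256(config.trait_path),
            "occurrence_csv": _sha256(config.occurrence_path),
        },
    }
    _atomic_write_text(paths["provenance_json"], _json_dumps(provenance))
    if config.render:
        paths["choropleth_png"] = out_dir / "ei_choropleth.png"
        render_choropleth(cells, paths["choropleth_png"])
    logger.info("pipeline wrote %d artifacts to %s", len(paths), out_dir)
    return PipelineResult(
        cells=cells,
        hotspot_report=report,
        summary=summary,
        rejections=rejected,
        municipality_table=muni_table,
        artifact_paths=paths,
    )


def render_choropleth(cells, path, metric: str = "ei") -> None:
    """Optional quick-look EI choropleth; the machine-readable layers are
    the contract, this is a curatorial convenience only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(8, 8))
    values = [getattr(c, metric) for c in cells.values()]
    vmax = max(values) if values else 1.0
    cmap = plt.get_cmap("viridis")
    for c in cells.values():
        west, south, east, north = c.bounds
        ax.add_patch(
            Rectangle(
                (west, south), east - west, north - south,
                facecolor=cmap(getattr(c, metric) / vmax if vmax else 0.0),
                edgecolor="none",
            )
        )
    ax.autoscale_view()
    ax.set_xlabel("longitude (dd)")
    ax.set_ylabel("latitude (dd)")
    ax.set_title(f"{metric} per {list(cells.values())[0].bounds[2] - list(cells.values())[0].bounds[0]:.3f} dd cell"
                 if cells else metric)
    fig.savefig(path, dpi=120)
    plt.close(fig)
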