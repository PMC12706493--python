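"""Shared fixtures: a tiny hand-written catalogue and record builders."""

from __future__ import annotations

import math

import pytest
from hypothesis import settings

from ethnogrid.occurrences import EnrichedOccurrence
from ethnogrid.trait_db import load_trait_db

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

# Three species: n_i = 2, 1, 1; one endemic; mixed habitats and risk status.
TRAIT_CSV = """\
scientificName,family,vernacularName,origin,endemic,growthForm,habitat,partUsed,iucnCategory,nom059Category,diseaseClasses,ailments
Croton cortesianus Kunth,Euphorbiaceae,palo blanco,native,false,shrub,wild;milpa,leaf;bark,LC,none,DS;DGS,DS:sores|rash;DGS:stomach pain
Kalanchoe pinnata (Lam.) Pers.,Crassulaceae,siempreviva,non-native,false,herb,home garden,leaf,not-evaluated,none,CBS,CBS:fright
Euphorbia peplus,Euphorbiaceae,,native,true,herb,wild,latex;whole plant,LC,none,NEC,
"""


@pytest.fixture
def trait_csv_path(tmp_path):
    path = tmp_path / "traits.csv"
    path.write_text(TRAIT_CSV)
    return path


@pytest.fixture
def tiny_db(trait_csv_path):
    return load_trait_db(trait_csv_path)


def make_enriched(species, lon, lat, classes, record_id="r1"):
    return EnrichedOccurrence(
        record_id=record_id,
        species_name_raw=species,
        species_name=species,
        longitude=lon,
        latitude=lat,
        disease_classes=frozenset(classes),
    )


def brute_force_cells(records, spec, n_total=19):
    """Independent per-record double-loop re-aggregation (test oracle)."""
    by_cell = {}
    for r in records:
        i = math.floor((r.longitude - spec.origin_lon) / spec.cell_size)
        j = math.floor((r.latitude - spec.origin_lat) / spec.cell_size)
        by_cell.setdefault((i, j), []).append(r)
    out = {}
    for idx, recs in by_cell.items():
        species = {}
        for r in recs:
            species[r.species_name] = r.disease_classes
        union = set()
        for c in species.values():
            union |= set(c)
        out[idx] = {
            "richness": len(species),
            "record_count": len(recs),
            "class_coverage": len(union),
            "ei": sum(len(c) for c in species.values()) / n_total,
            "species": frozenset(species),
        }
    return out
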