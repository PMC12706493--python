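"""Synthetic trait catalogues and occurrence sets with known ground truth.

The generator emulates the structure of a regional ethnomedicinal dataset:
a species pool with per-species disease-class sets (1..19 classes),
multi-label habitats / growth forms / parts / risk categories, and
occurrence points drawn as a uniform background plus Gaussian clusters
(planted hotspots) inside a bounding box.  Defaults are calibrated to the
published study conditions — 468 species in 113 families, class-count
buckets in proportion 121:88:259 for n_i = 1 / 2 / >= 3, 5,341 records, a
bounding box spanning the Huasteca study region — so pipeline tests run at
realistic scale without any downloads.

Everything is driven by one integer seed through numpy's Generator;
identical (config, seed) gives byte-identical output files.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .gridding import GridSpec, cell_of
from .trait_db import (
    DISEASE_CLASSES,
    SpeciesTraitRecord,
    TraitDB,
)

# Relative class popularity used when drawing which classes a species
# treats (most-treated classes first: symptoms NEC, skin, digestive, ...).
_CLASS_WEIGHTS = {
    "NEC": 270, "DS": 177, "DGS": 161, "CBS": 137, "CIPD": 135, "DRS": 75,
    "IPEC": 74, "PCP": 71, "DGUS": 64, "DMSC": 52, "DCS": 32, "MBND": 26,
    "DBBO": 24, "DEMP": 19, "DNS": 16, "DVS": 15, "ENMD": 13, "FIHS": 10,
    "NE": 3,
}


def _default_class_count_distribution() -> tuple[float, ...]:
    """P(n_i = k), k = 1..19: buckets 121:88:259, geometric tail within >= 3."""
    p = np.zeros(19)
    p[0] = 121.0
    p[1] = 88.0
    tail = 0.65 ** np.arange(17)  # k = 3..19
    p[2:] = 259.0 * tail / tail.sum()
    p /= p.sum()
    return tuple(p)


def _default_categorical_probs() -> dict:
    """Per-field probabilities matching the study's reported tallies."""
    n = 468.0
    return {
        "native": 418 / n,
        "endemic_given_native": 23 / 418,
        # multi-label Bernoulli per habitat (resampled if all-empty)
        "habitats": {
            "wild": 356 / n, "home garden": 237 / n, "milpa": 111 / n,
            "sugarcane plantation": 20 / n, "disturbed": 16 / n,
        },
        # single draw per species; minor forms share the remainder
        "growth_forms": {
            "herb": 228 / n, "tree": 100 / n, "shrub": 92 / n,
            "vine": 20 / n, "rosette": 12 / n, "creeping": 9 / n,
            "epiphyte": 7 / n,
        },
        "parts_used": {
            "leaf": 201 / n, "root": 136 / n, "bark": 69 / n, "stem": 0.10,
            "flower": 0.08, "fruit": 0.08, "seed": 0.05, "latex": 0.03,
            "whole plant": 0.06,
        },
        "iucn": {
            "LC": 128 / n, "DD": 5 / n, "EN": 4 / n, "VU": 2 / n,
            "CR": 1 / n, "NT": 1 / n, "not-evaluated": 327 / n,
        },
        "nom059": {
            "threatened": 2 / n, "special-protection": 1 / n,
            "endangered": 0.0, "none": 465 / n,
        },
    }


@dataclass(frozen=True)
class Cluster:
    """One planted Gaussian hotspot: records scatter around the center."""

    center_lon: float
    center_lat: float
    sd: float  # isotropic standard deviation, decimal degrees
    weight: float  # share of non-background records, relative to other clusters
    species_pool: tuple[str, ...] | None = None  # optional cluster-biased pool


def _default_clusters() -> tuple[Cluster, ...]:
    # Four hotspots at plausible in-region locations, one per named
    # municipality band; pure geometry, no real-data dependency.
    return (
        Cluster(-99.02, 21.62, 0.02, 0.30),
        Cluster(-98.72, 21.98, 0.02, 0.30),
        Cluster(-98.40, 21.35, 0.03, 0.25),
        Cluster(-97.85, 21.70, 0.03, 0.15),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults reproduce the study conditions."""

    seed: int = 0
    n_species: int = 468
    n_families: int = 113
    family_zipf: float = 1.3  # decay of species-per-family ranking
    class_count_distribution: tuple[float, ...] = field(
        default_factory=_default_class_count_distribution
    )
    categorical_probs: dict = field(default_factory=_default_categorical_probs)
    generate_ailments: bool = True
    n_records: int = 5341
    bbox: tuple[float, float, float, float] = (-99.2, 20.8, -97.5, 22.7)
    background_fraction: float = 0.35
    clusters: tuple[Cluster, ...] = field(default_factory=_default_clusters)
    species_zipf: float = 1.0  # abundance decay across the species pool
    n_municipalities: int = 0  # 0 = no synthetic municipality partition

    def validate(self) -> None:
        if self.n_families < 1 or self.n_species < self.n_families:
            raise ConfigError(
                f"need n_species >= n_families >= 1, got "
                f"{self.n_species} / {self.n_families}"
            )
        p = np.asarray(self.class_count_distribution, dtype=float)
        if p.shape != (19,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ConfigError("class_count_distribution must be 19 probabilities summing to 1")
        west, south, east, north = self.bbox
        if not (west < east and south < north):
            raise ConfigError(f"empty bounding box {self.bbox}")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ConfigError("background_fraction must be in [0, 1]")
        if any(c.weight < 0 or c.sd <= 0 for c in self.clusters):
            raise ConfigError("cluster weights must be >= 0 and sd > 0")
        if (
            self.background_fraction < 1.0
            and sum(c.weight for c in self.clusters) == 0
        ):
            raise ConfigError(
                "all cluster weights zero with background_fraction < 1"
            )


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    class_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    cluster_centers: list[tuple[float, float]] = field(default_factory=list)
    records_per_cluster: list[int] = field(default_factory=list)
    n_background: int = 0
    municipality_species: dict[str, set[str]] = field(default_factory=dict)
    municipality_records: dict[str, int] = field(default_factory=dict)

    def expected_cells(self, spec: GridSpec = GridSpec()) -> list[tuple[int, int]]:
        """Grid cell containing each planted cluster center."""
        return [cell_of(lon, lat, spec) for lon, lat in self.cluster_centers]

    def to_json(self, path) -> None:
        payload = {
            "class_sets": {k: sorted(v) for k, v in sorted(self.class_sets.items())},
            "cluster_centers": self.cluster_centers,
            "records_per_cluster": self.records_per_cluster,
            "n_background": self.n_background,
            "municipality_species": {
                k: sorted(v) for k, v in sorted(self.municipality_species.items())
            },
            "municipality_records": dict(sorted(self.municipality_records.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# --- name generation --------------------------------------------------------

_SYL = (
    "ba be bi bo bu ca ce ci co cu da de di do du fa fe fi fo fu ga ge gi go "
    "la le li lo lu ma me mi mo mu na ne ni no nu pa pe pi po pu ra re ri ro "
    "ru sa se si so su ta te ti to tu va ve vi vo xa ya za"
).split()
_EPITHET_ENDINGS = ("a", "um", "us", "is", "ii", "ensis", "ifolia", "oides", "ana")


def _unique_word(rng, n_syl, taken: set, suffix: str = "") -> str:
    for _ in range(50):
        w = "".join(_SYL[i] for i in rng.integers(0, len(_SYL), n_syl)) + suffix
        if w not in taken:
            taken.add(w)
            return w
    w = f"{w}{len(taken)}"
    taken.add(w)
    return w


# --- generators -------------------------------------------------------------


def generate_trait_db(config: SyntheticConfig) -> tuple[TraitDB, GroundTruth]:
    """Draw a full trait catalogue; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    probs = config.categorical_probs
    class_p = np.asarray(config.class_count_distribution, dtype=float)
    class_weights = np.array([_CLASS_WEIGHTS[c] for c in DISEASE_CLASSES], float)
    class_weights /= class_weights.sum()

    taken_fam: set[str] = set()
    families = [
        _unique_word(rng, 2, taken_fam, suffix="aceae").capitalize()
        for _ in range(config.n_families)
    ]
    fam_w = 1.0 / np.arange(1, config.n_families + 1) ** config.family_zipf
    fam_w /= fam_w.sum()

    taken_names: set[str] = set()
    genera_of_family: dict[str, list[str]] = {f: [] for f in families}
    taken_genera: set[str] = set()
    records: dict[str, SpeciesTraitRecord] = {}
    truth = GroundTruth()
    gf_names = list(probs["growth_forms"])
    gf_p = np.array([probs["growth_forms"][g] for g in gf_names], float)
    gf_p /= gf_p.sum()
    iucn_names = list(probs["iucn"])
    iucn_p = np.array([probs["iucn"][g] for g in iucn_names], float)
    iucn_p /= iucn_p.sum()
    nom_names = list(probs["nom059"])
    nom_p = np.array([probs["nom059"][g] for g in nom_names], float)
    nom_p /= nom_p.sum()

    for s in range(config.n_species):
        # every family gets at least one species, remainder Zipf-weighted
        if s < config.n_families:
            fam = families[s]
        else:
            fam = families[rng.choice(config.n_families, p=fam_w)]
        if genera_of_family[fam] and rng.random() < 0.25:
            genus = genera_of_family[fam][rng.integers(0, len(genera_of_family[fam]))]
        else:
            genus = _unique_word(rng, 3, taken_genera).capitalize()
            genera_of_family[fam].append(genus)
        epithet = _unique_word(
            rng, 2, taken_names, suffix=str(_EPITHET_ENDINGS[rng.integers(0, len(_EPITHET_ENDINGS))])
        )
        name = f"{genus} {epithet}"

        n_i = int(rng.choice(19, p=class_p)) + 1
        classes = frozenset(
            DISEASE_CLASSES[i]
            for i in rng.choice(19, size=n_i, replace=False, p=class_weights)
        )
        ailments = {}
        if config.generate_ailments:
            ailments = {
                c: frozenset(
                    f"{c.lower()}-symptom-{k + 1}"
                    for k in range(int(rng.integers(1, 4)))
                )
                for c in sorted(classes)
            }
        native = rng.random() < probs["native"]
        endemic = bool(native and rng.random() < probs["endemic_given_native"])
        habitats = frozenset(
            h for h, p in probs["habitats"].items() if rng.random() < p
        ) or frozenset({"wild"})
        parts = frozenset(
            p for p, q in probs["parts_used"].items() if rng.random() < q
        ) or frozenset({"leaf"})
        records[name] = SpeciesTraitRecord(
            species_name=name,
            family=fam,
            genus=genus,
            common_names=tuple(
                f"{epithet}-name-{k + 1}" for k in range(int(rng.integers(0, 3)))
            ),
            origin="native" if native else "non-native",
            endemic=endemic,
            growth_forms=frozenset({gf_names[rng.choice(len(gf_names), p=gf_p)]}),
            habitats=habitats,
            parts_used=parts,
            iucn_category=iucn_names[rng.choice(len(iucn_names), p=iucn_p)],
            nom059_category=nom_names[rng.choice(len(nom_names), p=nom_p)],
            disease_classes=classes,
            ailments=ailments,
        )
        truth.class_sets[name] = classes
    return TraitDB(records=records), truth


def _municipality_of(lon: float, config: SyntheticConfig) -> str:
    """Synthetic partition: equal-width longitude bands across the bbox."""
    west, _, east, _ = config.bbox
    k = config.n_municipalities
    band = min(int((lon - west) / (east - west) * k), k - 1)
    return f"Muni-{band + 1:02d}"


def generate_occurrences(
    config: SyntheticConfig, db: TraitDB
) -> tuple[list[dict], GroundTruth]:
    """Draw occurrence rows: uniform background + Gaussian cluster mixture.

    Cluster draws falling outside the bounding box are resampled (not
    clipped), so edge density is not inflated.  Rows come back in the CSV
    dialect ``load_occurrences`` reads; use :func:`write_occurrences_csv`
    to materialize them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from traits
    west, south, east, north = config.bbox
    names = db.species_names
    sp_w = 1.0 / np.arange(1, len(names) + 1) ** config.species_zipf
    sp_w /= sp_w.sum()

    n_bg = int(round(config.background_fraction * config.n_records))
    n_cl = config.n_records - n_bg
    cl_w = np.array([c.weight for c in config.clusters], float)
    if n_cl > 0 and cl_w.sum() > 0:
        per_cluster = rng.multinomial(n_cl, cl_w / cl_w.sum())
    else:
        per_cluster = np.zeros(len(config.clusters), dtype=int)
        n_bg = config.n_records

    truth = GroundTruth(
        class_sets={n: db[n].disease_classes for n in names},
        cluster_centers=[(c.center_lon, c.center_lat) for c in config.clusters],
        records_per_cluster=[int(x) for x in per_cluster],
        n_background=int(n_bg),
    )

    def draw_species(cluster: Cluster | None) -> str:
        if cluster is not None and cluster.species_pool:
            return cluster.species_pool[rng.integers(0, len(cluster.species_pool))]
        return names[rng.choice(len(names), p=sp_w)]

    points: list[tuple[float, float, Cluster | None]] = []
    for _ in range(n_bg):
        points.append(
            (float(rng.uniform(west, east)), float(rng.uniform(south, north)), None)
        )
    for cluster, m in zip(config.clusters, per_cluster):
        for _ in range(int(m)):
            while True:
                lon = float(rng.normal(cluster.center_lon, cluster.sd))
                lat = float(rng.normal(cluster.center_lat, cluster.sd))
                if west <= lon <= east and south <= lat <= north:
                    break
            points.append((lon, lat, cluster))

    rows: list[dict] = []
    for i, (lon, lat, cluster) in enumerate(points, start=1):
        name = draw_species(cluster)
        year = (
            int(rng.integers(1970, 2025))
            if rng.random() < 0.87
            else int(rng.integers(1930, 1970))
        )
        muni = (
            _municipality_of(lon, config) if config.n_municipalities > 0 else ""
        )
        rows.append(
            {
                "occurrenceID": f"synth-{i}",
                "scientificName": name,
                "decimalLongitude": repr(lon),
                "decimalLatitude": repr(lat),
                "year": str(year),
                "institutionCode": "SLPM" if rng.random() < 0.6 else "GBIF",
                "municipality": muni,
                "catalogNumber": f"V{i:06d}",
            }
        )
        if config.n_municipalities > 0:
            truth.municipality_species.setdefault(muni, set()).add(name)
            truth.municipality_records[muni] = (
                truth.municipality_records.get(muni, 0) + 1
            )
    return rows, truth


_OCC_COLUMNS = (
    "occurrenceID", "scientificName", "decimalLongitude", "decimalLatitude",
    "year", "institutionCode", "municipality", "catalogNumber",
)


def write_occurrences_csv(rows: list[dict], path) -> None:
    """Write generated rows as CSV; zero rows still produces a header."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_OCC_COLUMNS, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


def generate_fixture_pair(
    config: SyntheticConfig, trait_path, occurrence_path, truth_path=None
) -> GroundTruth:
    """Write a matched (trait CSV, occurrence CSV) pair ready for the loaders."""
    db, _ = generate_trait_db(config)
    db.to_csv(trait_path)
    rows, truth = generate_occurrences(config, db)
    write_occurrences_csv(rows, occurrence_path)
    if truth_path is not None:
        truth.to_json(truth_path)
    return truth
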