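"""Medicinal-plant trait catalogue: disease-class scheme, species records, tallies.

The catalogue describes each medicinal species by taxonomy, origin and
endemism, growth forms, source habitats, plant parts used, conservation risk
status (IUCN Red List and the Mexican NOM-059-SEMARNAT-2010 norm), and the
set of disease classes it treats.  Disease classes follow the chapters of
ICD-11 (18 classes) plus culture-bound syndromes (CBS) as a 19th class; the
size of a species' class set, ``n_i``, is the quantity the ethnomedicinal
index sums over.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ValidationError

# --- disease-class scheme ---------------------------------------------------

#: Code -> full label.  18 ICD-11 chapter-derived classes plus CBS.
DISEASE_CLASS_LABELS: dict[str, str] = {
    "CIPD": "Certain infectious or parasitic diseases",
    "DBBO": "Diseases of the blood or blood-forming organs",
    "DCS": "Diseases of the circulatory system",
    "DGS": "Diseases of the digestive system",
    "DEMP": "Diseases of the ear or mastoid process",
    "DVS": "Diseases of the visual system",
    "DGUS": "Diseases of the genitourinary system",
    "DMSC": "Diseases of the musculoskeletal system or connective tissue",
    "DNS": "Diseases of the nervous system",
    "DRS": "Diseases of the respiratory system",
    "DS": "Diseases of the skin",
    "ENMD": "Endocrine, nutritional or metabolic diseases",
    "FIHS": "Factors influencing health status or contact with health services",
    "IPEC": "Injury, poisoning or certain other consequences of external causes",
    "MBND": "Mental, behavioural or neurodevelopmental disorders",
    "NE": "Neoplasms",
    "PCP": "Pregnancy, childbirth or the puerperium",
    "NEC": "Symptoms, signs or clinical findings, not elsewhere classified",
    "CBS": "Culture-bound syndromes",
}

#: The 19 class codes, in canonical (ICD-chapter, then CBS) order.
DISEASE_CLASSES: tuple[str, ...] = tuple(DISEASE_CLASS_LABELS)

#: Total number of disease classes, the default N in the ethnomedicinal index.
N_CLASSES: int = len(DISEASE_CLASSES)

# --- controlled vocabularies ------------------------------------------------

GROWTH_FORMS = frozenset(
    {"herb", "tree", "shrub", "vine", "rosette", "creeping", "epiphyte"}
)
HABITATS = frozenset(
    {"wild", "home garden", "milpa", "sugarcane plantation", "disturbed"}
)
PARTS_USED = frozenset(
    {"leaf", "root", "bark", "stem", "flower", "fruit", "seed", "latex",
     "whole plant", "resin", "sap", "branch"}
)
IUCN_CATEGORIES = frozenset({"LC", "NT", "VU", "EN", "CR", "DD", "not-evaluated"})
NOM059_CATEGORIES = frozenset({"threatened", "special-protection", "endangered", "none"})
ORIGINS = frozenset({"native", "non-native"})

#: Infraspecific rank markers preserved during name canonicalization.
_RANK_MARKERS = {"var.", "subsp.", "ssp.", "f.", "fo.", "forma", "subvar.", "cv."}


def canonicalize_name(raw_name: str, strip_authors: bool = True) -> str:
    """Normalize a scientific name to canonical binomial form.

    Whitespace is trimmed and collapsed, the genus capitalized, the specific
    epithet lower-cased.  With ``strip_authors`` (default) author strings
    after the epithet are dropped, while infraspecific rank markers
    (var., subsp., f., ...) and their epithets are kept.  This is purely
    syntactic: no synonym or spelling resolution is attempted.

    >>> canonicalize_name("  euphorbia   Peplus L. ")
    'Euphorbia peplus'
    """
    s = " ".join(str(raw_name).split())
    if not s:
        raise ValidationError("species name empty after trimming whitespace")
    tokens = s.split(" ")
    if len(tokens) == 1:
        return tokens[0].capitalize()
    out = [tokens[0].capitalize(), tokens[1].lower()]
    rest = tokens[2:]
    if not strip_authors:
        return " ".join(out + rest)
    k = 0
    while k < len(rest):
        tok = rest[k]
        if tok.lower() in _RANK_MARKERS and k + 1 < len(rest):
            out.append(tok.lower())
            out.append(rest[k + 1].lower())
            k += 2
        else:
            k += 1
    return " ".join(out)


# --- species record ---------------------------------------------------------


@dataclass(frozen=True)
class SpeciesTraitRecord:
    """One medicinal species and its ethnomedicinal traits.

    ``disease_classes`` holds the class codes the species treats; its size is
    the species' n_i.  ``ailments`` optionally maps a class code to the set
    of named diseases/symptoms treated within that class.
    """

    species_name: str
    family: str
    genus: str
    origin: str
    endemic: bool
    growth_forms: frozenset[str]
    habitats: frozenset[str]
    parts_used: frozenset[str]
    disease_classes: frozenset[str]
    iucn_category: str = "not-evaluated"
    nom059_category: str = "none"
    common_names: tuple[str, ...] = ()
    ailments: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        errors = self._invariant_errors()
        if errors:
            raise ValidationError(errors)

    def _invariant_errors(self) -> list[str]:
        e = []
        name = self.species_name
        if self.genus != name.split(" ")[0]:
            e.append(f"{name}: genus {self.genus!r} != first name token")
        if self.origin not in ORIGINS:
            e.append(f"{name}: origin {self.origin!r} not in {sorted(ORIGINS)}")
        if self.endemic and self.origin != "native":
            e.append(f"{name}: endemic species must be native")
        if not self.growth_forms:
            e.append(f"{name}: empty growth-form set")
        if not self.habitats:
            e.append(f"{name}: empty habitat set")
        if not self.parts_used:
            e.append(f"{name}: empty parts-used set")
        for val, vocab, what in (
            (self.growth_forms, GROWTH_FORMS, "growth form"),
            (self.habitats, HABITATS, "habitat"),
            (self.parts_used, PARTS_USED, "part used"),
        ):
            for v in sorted(set(val) - vocab):
                e.append(f"{name}: unknown {what} {v!r}")
        if self.iucn_category not in IUCN_CATEGORIES:
            e.append(f"{name}: unknown IUCN category {self.iucn_category!r}")
        if self.nom059_category not in NOM059_CATEGORIES:
            e.append(f"{name}: unknown NOM-059 category {self.nom059_category!r}")
        if not self.disease_classes:
            e.append(f"{name}: empty disease-class set")
        for c in sorted(set(self.disease_classes) - set(DISEASE_CLASSES)):
            e.append(f"{name}: unknown disease-class code {c!r}")
        for c in sorted(set(self.ailments) - set(self.disease_classes)):
            e.append(f"{name}: ailments listed for class {c!r} not in disease_classes")
        return e

    @property
    def n_classes(self) -> int:
        """n_i: number of disease classes this species treats."""
        return len(self.disease_classes)


@dataclass(frozen=True)
class TraitDB:
    """The trait catalogue, keyed by canonical species name."""

    records: dict[str, SpeciesTraitRecord]

    def __post_init__(self):
        if not self.records:
            raise ValidationError("trait database is empty")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, species_name: str) -> bool:
        return species_name in self.records

    def __getitem__(self, species_name: str) -> SpeciesTraitRecord:
        return self.records[species_name]

    @property
    def species_names(self) -> list[str]:
        return list(self.records)

    def derived_n_classes(self) -> int:
        """Number of distinct classes actually used across the catalogue."""
        union: set[str] = set()
        for rec in self:
            union |= rec.disease_classes
        return len(union)

    def to_csv(self, path) -> None:
        """Serialize with the default column names; inverse of load_trait_db."""
        rows = []
        for rec in self.records.values():
            rows.append(
                {
                    "scientificName": rec.species_name,
                    "family": rec.family,
                    "vernacularName": ";".join(rec.common_names),
                    "origin": rec.origin,
                    "endemic": "true" if rec.endemic else "false",
                    "growthForm": ";".join(sorted(rec.growth_forms)),
                    "habitat": ";".join(sorted(rec.habitats)),
                    "partUsed": ";".join(sorted(rec.parts_used)),
                    "iucnCategory": rec.iucn_category,
                    "nom059Category": rec.nom059_category,
                    "diseaseClasses": ";".join(
                        c for c in DISEASE_CLASSES if c in rec.disease_classes
                    ),
                    "ailments": ";".join(
                        f"{c}:{'|'.join(sorted(rec.ailments[c]))}"
                        for c in DISEASE_CLASSES
                        if c in rec.ailments
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)


#: Default column mapping for trait CSVs (Darwin-Core-ish names).
DEFAULT_TRAIT_COLUMNS: dict[str, str] = {
    "species_name": "scientificName",
    "family": "family",
    "common_names": "vernacularName",
    "origin": "origin",
    "endemic": "endemic",
    "growth_forms": "growthForm",
    "habitats": "habitat",
    "parts_used": "partUsed",
    "iucn_category": "iucnCategory",
    "nom059_category": "nom059Category",
    "disease_classes": "diseaseClasses",
    "ailments": "ailments",
}

_REQUIRED_TRAIT_FIELDS = (
    "species_name",
    "family",
    "origin",
    "growth_forms",
    "habitats",
    "parts_used",
    "disease_classes",
)

_TRUE_STRINGS = {"true", "yes", "1", "t", "y"}
_FALSE_STRINGS = {"false", "no", "0", "f", "n", ""}


def _read_delimited(path, sep=None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _split_multi(cell: str, delim: str) -> list[str]:
    return [p.strip() for p in cell.split(delim) if p.strip()]


def _parse_ailments(cell: str, delim: str) -> dict[str, frozenset[str]]:
    """Parse ``CODE:a|b;CODE2:c`` cells into a class -> ailment-set mapping."""
    out: dict[str, frozenset[str]] = {}
    for part in _split_multi(cell, delim):
        if ":" not in part:
            raise ValueError(f"ailment entry {part!r} lacks 'CODE:' prefix")
        code, _, names = part.partition(":")
        out[code.strip()] = frozenset(
            n.strip() for n in names.split("|") if n.strip()
        )
    return out


def load_trait_db(
    path,
    column_map: dict[str, str] | None = None,
    multi_delimiter: str = ";",
    strip_authors: bool = True,
    sep: str | None = None,
) -> TraitDB:
    """Load and validate a trait catalogue from delimited text.

    Multi-valued cells (habitats, growth forms, parts, classes, common
    names) are split on ``multi_delimiter``.  Validation is collect-then-
    fail: every offending row is reported in a single ValidationError.
    Duplicate canonical species names, unknown disease-class codes and
    empty class sets are hard errors.
    """
    columns = dict(DEFAULT_TRAIT_COLUMNS)
    if column_map:
        columns.update(column_map)
    df = _read_delimited(path, sep=sep)
    missing = [
        columns[f] for f in _REQUIRED_TRAIT_FIELDS if columns[f] not in df.columns
    ]
    if missing:
        raise ValidationError([f"missing required column {c!r}" for c in missing])

    def cell(row, fld, default=""):
        col = columns.get(fld)
        return str(row[col]).strip() if col in df.columns else default

    errors: list[str] = []
    records: dict[str, SpeciesTraitRecord] = {}
    first_row_of: dict[str, int] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rowd = dict(zip(df.columns, row))
        raw_name = cell(rowd, "species_name")
        try:
            name = canonicalize_name(raw_name, strip_authors=strip_authors)
        except ValidationError:
            errors.append(f"row {idx}: species name empty")
            continue
        endemic_raw = cell(rowd, "endemic").lower()
        if endemic_raw in _TRUE_STRINGS:
            endemic = True
        elif endemic_raw in _FALSE_STRINGS:
            endemic = False
        else:
            errors.append(f"row {idx} ({name}): unreadable endemic flag {endemic_raw!r}")
            continue
        try:
            ailments = _parse_ailments(cell(rowd, "ailments"), multi_delimiter)
        except ValueError as exc:
            errors.append(f"row {idx} ({name}): {exc}")
            continue
        try:
            rec = SpeciesTraitRecord(
                species_name=name,
                family=cell(rowd, "family"),
                genus=name.split(" ")[0],
                common_names=tuple(
                    _split_multi(cell(rowd, "common_names"), multi_delimiter)
                ),
                origin=cell(rowd, "origin").lower(),
                endemic=endemic,
                growth_forms=frozenset(
                    v.lower() for v in _split_multi(cell(rowd, "growth_forms"), multi_delimiter)
                ),
                habitats=frozenset(
                    v.lower() for v in _split_multi(cell(rowd, "habitats"), multi_delimiter)
                ),
                parts_used=frozenset(
                    v.lower() for v in _split_multi(cell(rowd, "parts_used"), multi_delimiter)
                ),
                iucn_category=cell(rowd, "iucn_category") or "not-evaluated",
                nom059_category=cell(rowd, "nom059_category").lower() or "none",
                disease_classes=frozenset(
                    _split_multi(cell(rowd, "disease_classes").upper(), multi_delimiter)
                ),
                ailments=ailments,
            )
        except ValidationError as exc:
            errors.extend(f"row {idx}: {m}" for m in exc.errors)
            continue
        if name in records:
            errors.append(
                f"row {idx}: duplicate species {name!r} (first seen row {first_row_of[name]})"
            )
            continue
        records[name] = rec
        first_row_of[name] = idx
    if errors:
        raise ValidationError(errors)
    return TraitDB(records=records)


# --- summaries --------------------------------------------------------------


def _sorted_tally(counter: Counter) -> dict:
    """Deterministic tally ordering: count descending, then key ascending."""
    return dict(sorted(counter.items(), key=lambda kv: (-kv[1], str(kv[0]))))


def summarize_taxonomy(db: TraitDB) -> dict:
    """Species / family / genus totals and per-family, per-genus counts."""
    fam = Counter(rec.family for rec in db)
    gen = Counter(rec.genus for rec in db)
    return {
        "n_species": len(db),
        "n_families": len(fam),
        "n_genera": len(gen),
        "species_per_family": _sorted_tally(fam),
        "species_per_genus": _sorted_tally(gen),
    }


_MULTI_FIELDS = {"habitats", "growth_forms", "parts_used"}
_SINGLE_FIELDS = {"origin", "endemic", "iucn_category", "nom059_category"}


def summarize_categorical(db: TraitDB, field_name: str) -> dict:
    """Tally value -> species count for a trait field.

    Multi-label fields (habitats, growth forms, parts) count a species once
    per value it carries, so their tallies may sum past the species total;
    single-label fields partition the catalogue.
    """
    if field_name not in _MULTI_FIELDS | _SINGLE_FIELDS:
        raise ValidationError(f"unknown categorical field {field_name!r}")
    tally: Counter = Counter()
    for rec in db:
        if field_name in _MULTI_FIELDS:
            tally.update(getattr(rec, field_name))
        elif field_name == "endemic":
            tally["endemic" if rec.endemic else "not-endemic"] += 1
        else:
            tally[getattr(rec, field_name)] += 1
    return _sorted_tally(tally)


def class_count_distribution(db: TraitDB) -> dict:
    """Histogram of n_i (classes treated per species) with both bucketings.

    Reported buckets: n_i = 1, n_i = 2, and the remainder both as
    ``n_3_or_more`` (n_i >= 3) and as ``n_3`` / ``n_more_than_3`` so either
    reading of a "more than three" summary can be checked.
    """
    hist = Counter(rec.n_classes for rec in db)
    return {
        "histogram": dict(sorted(hist.items())),
        "n_1": hist.get(1, 0),
        "n_2": hist.get(2, 0),
        "n_3_or_more": sum(v for k, v in hist.items() if k >= 3),
        "n_3": hist.get(3, 0),
        "n_more_than_3": sum(v for k, v in hist.items() if k > 3),
    }


def disease_class_table(db: TraitDB) -> pd.DataFrame:
    """Per-class overview: distinct ailment count (if recorded) and species count.

    All 19 classes are emitted, zero-count classes included.  The ailment
    column is absent (all-NA) when no record carries ailment annotations.
    """
    species_count = Counter()
    ailments: dict[str, set[str]] = {c: set() for c in DISEASE_CLASSES}
    any_ailments = False
    for rec in db:
        for c in rec.disease_classes:
            species_count[c] += 1
        for c, names in rec.ailments.items():
            ailments[c] |= names
            any_ailments = True
    rows = []
    for code in DISEASE_CLASSES:
        rows.append(
            {
                "class_code": code,
                "class_label": DISEASE_CLASS_LABELS[code],
                "n_ailments": len(ailments[code]) if any_ailments else pd.NA,
                "n_species": species_count.get(code, 0),
            }
        )
    return pd.DataFrame(rows)
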