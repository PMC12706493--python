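# Methods

## The mapping model

The package operationalizes a three-layer model of regional ethnomedicinal
diversity:

1. **Catalogue layer.** Each medicinal species carries a non-empty set of
   disease classes it treats, drawn from a fixed 19-class scheme — the 18
   ICD-11-chapter-derived classes plus culture-bound syndromes (CBS), the
   locally defined illness categories (e.g. spirit-loss conditions) that
   fall outside ICD-11.  The size of the set, nᵢ, measures how broadly a
   species is used.  Other traits (origin, endemism, growth forms,
   habitats, parts used, IUCN and NOM-059-SEMARNAT-2010 risk categories)
   are descriptive and feed tallies only.
2. **Occurrence layer.** Georeferenced records (WGS84 decimal degrees,
   Darwin-Core-like CSV) place species in space.  Records are evidence of
   presence; their multiplicity is reported but never enters richness or
   the index.
3. **Grid layer.** An equal-angle grid of `cell_size` decimal degrees
   (default 0.045, ≈ 5 km at these latitudes) partitions the plane.  Per
   occupied cell: richness SR = |unique species|, class coverage =
   |union of member class sets|, and the ethnomedicinal index
   EI = Σᵢ nᵢ / N over the unique species, with N = 19 by default (or
   `derive_n`, which uses the number of classes actually present in the
   catalogue).  EI rewards the co-occurrence of many broadly used species:
   it is bounded by SR/N ≤ EI ≤ SR.

Assumptions worth stating: coordinates are trusted as given (no geodesy,
no re-projection, no uncertainty radii); species identity is an exact
match on the syntactically canonicalized binomial (no synonym resolution —
nomenclature curation is upstream of this package); and equal-angle cells
are treated as comparable units even though their metric area varies
slightly with latitude.

## Cleaning rules

Cleaning rejects, with a per-record logged reason: missing or unparseable
coordinates; coordinates outside [−180, 180] × [−90, 90]; exact (0, 0)
coordinates, which in aggregator exports are almost always a missing-value
placeholder rather than a Gulf of Guinea record; points outside an optional
bounding box; and species absent from the catalogue after
canonicalization.  Exact duplicates of (species, lon, lat) are *kept* by
default — herbarium duplicates are real specimens and no dedup rule is
part of the method — with an optional `dedupe` flag; likewise year
filtering exists (`min_year`) but is off by default.  Cleaning never
raises: accepted + rejected always equals the input count, and the
operation is idempotent.

## Grid anchoring and cell membership

The grid origin (the corner that cell edges are multiples of `cell_size`
from) is a free parameter that published per-cell counts rarely state.
The default anchors edges at integer multiples of 0.045° from (0, 0);
`grid_origin` overrides this, e.g. with the data-extent minimum.  Cell
membership is half-open ([west, east) × [south, north)): a point exactly
on a shared edge belongs to the cell whose west/south edge it lies on.
This makes binning a deterministic partition; the trade-off is that any
comparison against maps gridded with a different anchor can shift
individual points across cell boundaries, so per-cell values should only
be compared between runs that share an anchor.

## Hotspot selection

Cells are ranked by one metric (EI, richness, or class coverage),
descending, with ties broken by (row, column) ascending so the order is a
deterministic function of the cell map alone.  Selection is either top-k
or metric ≥ threshold; the applied rule is echoed into the report.  The
default rule is EI ≥ 15.0 — a round cutoff in the value range where
regional high-EI cells separate from the background in catalogue-scale
data; it is a reporting default, not a statistical claim, and thresholds
are monotone (a lower threshold selects a superset).  Formal significance
testing of hotspots (e.g. permutation nulls) is a documented extension,
not implemented.

Municipality aggregation uses the record's municipality attribute, or
point-in-polygon against user GeoJSON boundaries (shapely `covers`, first
polygon in file order wins on shared boundaries); unresolved records are
tallied under "unassigned".  Species are counted once per municipality
with no global dedup, so municipal richness values deliberately do not sum
to regional richness.

## Synthetic data: what it emulates, and what it does not

`SyntheticConfig` defaults encode the study conditions the package is
sized for: 468 species in 113 families, 5,341 records, bounding box
lon −99.2..−97.5 / lat 20.8..22.7.  Families and species abundances decay
as Zipf laws (exponents 1.3 and 1.0), giving the usual few-large-many-
small family structure and a realistic ~4 % of species never observed at
5,341 records.  The nᵢ distribution puts mass 121:88:259 (of 468) on
nᵢ = 1 / 2 / ≥ 3, with a truncated geometric tail (ratio 0.65) over 3..19
— the within-bucket shape is a modelling choice, as only bucket totals are
typically reported.  Class membership, habitats, growth forms, parts and
risk categories are drawn with probabilities matching the corresponding
catalogue tallies.  Spatially, records are a mixture of a uniform
background over the bounding box and isotropic Gaussian clusters (planted
hotspots); cluster draws falling outside the box are resampled, not
clipped, so edge density is not inflated.  An optional partition into
equal-width longitude bands provides synthetic municipalities with exact
ground-truth composition.

Not emulated: collection bias (roadside and river effects, duplicate
vouchers, collector hot-streaks), coordinate error and rounding grids,
taxonomic drift between the catalogue and the occurrence source, and
spatial correlation between a species' traits and its range.  Passing
recovery tests therefore shows the pipeline correctly recovers structure
*that is present in the data*; it does not show robustness to the biases
of real aggregator exports, which must be addressed in curation.

## Numerical and design choices

- EI is kept at full floating precision everywhere machine-readable;
  1-decimal rounding is applied only in the plain-text report.
- Validation of catalogue files is collect-then-fail: every bad row is
  reported in one pass.  Missing risk status maps to explicit
  "not-evaluated" / "none" so tallies are total.
- Multi-valued CSV cells split on ";" (configurable) to avoid colliding
  with botanical author commas.
- Tallies order by count descending then name ascending; cell exports
  order by (row, column); every output is a deterministic function of the
  inputs, and the provenance record carries the config, input SHA-256
  checksums and package version (and deliberately no timestamp, so
  re-runs of the same config produce byte-identical bundles).
- Ranking ties and the degenerate cases — empty record lists, empty cells
  (never emitted), selections that match nothing (valid, warned) — are
  all defined rather than left to dict ordering.
- The brute-force re-aggregation oracle used in tests rebuilds every cell
  independently per record and is kept separate from the library path.

## Problem sizes in the shipped checks

Unit and property tests run at desk scale (≤ 200 records per random
instance, 1,000 random cells for the EI bound, 50 oracle instances).
Hotspot-recovery checks use 100 replicate simulations of 300 records with
one planted cluster (sd 0.01°, 80 % of records); the end-to-end check and
the acceptance script run one full catalogue-scale simulation (468
species, 5,341 records) plus 50 recovery replicates.  The whole suite
completes in a few seconds on one CPU.

## Known limitations

- No synonym or fuzzy name matching: a catalogue/occurrence name mismatch
  is a rejection, not a correction.
- Equal-angle cells are nominally, not exactly, equal-area.
- The EI weights every disease class equally and every species' classes
  equally; no informant-consensus or use-report weighting is modelled.
- Hotspot selection is descriptive; no null model is fitted.
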