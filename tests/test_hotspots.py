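"""Hotspot ranking, selection rules, and municipality aggregation."""

import dataclasses
import random

import pytest

from ethnogrid.errors import ValidationError
from ethnogrid.gridding import GridSpec, aggregate_cells
from ethnogrid.hotspots import municipality_summary, rank_cells, select_hotspots
from ethnogrid.synthetic import (
    Cluster,
    SyntheticConfig,
    generate_occurrences,
    generate_trait_db,
)
from ethnogrid.occurrences import clean_occurrences, join_traits

from conftest import make_enriched
from test_gridding import random_records


def cells_with_ei(values):
    """Build a cell map whose EI values (ordered by (j, i)) are `values`."""
    recs = []
    for k, v in enumerate(values):
        n = round(v * 19)
        lon, lat = -99.0 + 0.045 * k + 0.01, 21.0 + 0.01
        for s in range(n):  # n species with one class each -> EI = n/19
            recs.append(make_enriched(f"Sp a{k}b{s}", lon, lat, {"DS"}, f"{k}-{s}"))
    return aggregate_cells(recs)


class TestRankCells:
    def test_ties_broken_by_row_then_column(self):
        cells = cells_with_ei([5 / 19, 2 / 19, 5 / 19])
        ranked = rank_cells(cells, "ei")
        assert [v for _, v in ranked] == pytest.approx([5 / 19, 5 / 19, 2 / 19])
        first, second = ranked[0][0], ranked[1][0]
        assert (first[1], first[0]) < (second[1], second[0])

    def test_singleton(self):
        cells = cells_with_ei([1 / 19])
        assert len(rank_cells(cells, "richness")) == 1

    def test_permutation_of_input_changes_nothing(self):
        rng = random.Random(11)
        cells = aggregate_cells(random_records(rng, 150))
        ranked = rank_cells(cells, "ei")
        items = list(cells.items())
        rng.shuffle(items)
        assert rank_cells(dict(items), "ei") == ranked
        assert sorted(ij for ij, _ in ranked) == sorted(cells)

    def test_unknown_metric_and_empty_map_rejected(self):
        cells = cells_with_ei([1 / 19])
        with pytest.raises(ValidationError):
            rank_cells(cells, "voltage")
        with pytest.raises(ValidationError):
            rank_cells({}, "ei")

    def test_planted_cluster_cell_ranks_first(self):
        config = SyntheticConfig(
            seed=42, n_species=40, n_families=8, n_records=400,
            background_fraction=0.2,
            clusters=(Cluster(-98.4, 21.7, 0.01, 1.0),),
        )
        db, _ = generate_trait_db(config)
        rows, truth = generate_occurrences(config, db)
        accepted, _ = clean_occurrences(rows, db)
        cells = aggregate_cells(join_traits(accepted, db), GridSpec())
        top_cell = rank_cells(cells, "ei")[0][0]
        assert top_cell == truth.expected_cells(GridSpec())[0]


class TestSelectHotspots:
    def test_threshold_rule(self):
        ranked = [((0, 0), 46.7), ((1, 0), 21.8), ((2, 0), 17.5), ((3, 0), 3.2)]
        report = select_hotspots(ranked, threshold=15.0)
        assert len(report.selection) == 3
        assert report.rule == {"type": "threshold", "threshold": 15.0}

    def test_top_k_rule(self):
        ranked = [((0, 0), 46.7), ((1, 0), 21.8)]
        report = select_hotspots(ranked, k=1)
        assert report.selection == [((0, 0), 46.7)]

    def test_threshold_above_maximum_gives_empty_selection(self):
        report = select_hotspots([((0, 0), 3.0)], threshold=100.0)
        assert report.selection == []

    def test_monotone_nesting_of_thresholds(self):
        rng = random.Random(5)
        ranked = rank_cells(aggregate_cells(random_records(rng, 150)), "ei")
        lo = {ij for ij, _ in select_hotspots(ranked, threshold=0.1).selection}
        hi = {ij for ij, _ in select_hotspots(ranked, threshold=0.3).selection}
        assert hi <= lo

    @pytest.mark.parametrize(
        "kwargs", [{}, {"k": 1, "threshold": 1.0}, {"k": 0}, {"k": -2},
                   {"threshold": float("nan")}, {"threshold": float("inf")}],
    )
    def test_invalid_rules_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            select_hotspots([((0, 0), 1.0)], **kwargs)


class TestMunicipalitySummary:
    def test_disjoint_species_sets(self):
        recs = (
            [make_enriched(f"Aa sp{k}", -98.9, 21.1, {"DS"}, f"a{k}") for k in range(2)]
            + [make_enriched(f"Bb sp{k}", -98.1, 21.1, {"CBS"}, f"b{k}") for k in range(3)]
        )
        recs = [
            dataclasses.replace(r, municipality="East" if r.longitude > -98.5 else "West")
            for r in recs
        ]
        df = municipality_summary(recs).set_index("municipality")
        assert df.loc["West", "richness"] == 2
        assert df.loc["East", "richness"] == 3

    def test_species_in_two_municipalities_counted_in_both(self):
        recs = [
            make_enriched("Aa aa", -98.9, 21.1, {"DS"}, "1"),
            make_enriched("Aa aa", -98.1, 21.1, {"DS"}, "2"),
        ]
        recs = [
            dataclasses.replace(r, municipality=m)
            for r, m in zip(recs, ["West", "East"])
        ]
        df = municipality_summary(recs)
        assert list(df["richness"]) == [1, 1]

    def test_missing_attribute_goes_to_unassigned(self):
        recs = [make_enriched("Aa aa", -98.9, 21.1, {"DS"}, "1")]
        df = municipality_summary(recs)
        assert list(df["municipality"]) == ["unassigned"]

    def test_point_in_polygon_first_match_wins(self):
        boundaries = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "properties": {"name": "Left"},
                 "geometry": {"type": "Polygon", "coordinates": [[
                     [-99.0, 21.0], [-98.5, 21.0], [-98.5, 22.0],
                     [-99.0, 22.0], [-99.0, 21.0]]]}},
                {"type": "Feature", "properties": {"name": "Right"},
                 "geometry": {"type": "Polygon", "coordinates": [[
                     [-98.5, 21.0], [-98.0, 21.0], [-98.0, 22.0],
                     [-98.5, 22.0], [-98.5, 21.0]]]}},
            ],
        }
        recs = [
            make_enriched("Aa aa", -98.7, 21.5, {"DS"}, "1"),
            make_enriched("Bb bb", -98.2, 21.5, {"CBS"}, "2"),
            make_enriched("Cc cc", -98.5, 21.5, {"NEC"}, "3"),  # shared edge
        ]
        df = municipality_summary(recs, boundary_source=boundaries)
        by = df.set_index("municipality")
        assert by.loc["Left", "record_count"] == 2  # edge point -> first polygon
        assert by.loc["Right", "record_count"] == 1

    def test_synthetic_partition_recovered_exactly(self):
        config = SyntheticConfig(
            seed=9, n_species=30, n_families=6, n_records=200,
            n_municipalities=3,
        )
        db, _ = generate_trait_db(config)
        rows, truth = generate_occurrences(config, db)
        accepted, _ = clean_occurrences(rows, db)
        df = municipality_summary(join_traits(accepted, db)).set_index("municipality")
        assert set(df.index) == set(truth.municipality_species)
        for muni, species in truth.municipality_species.items():
            assert df.loc[muni, "richness"] == len(species)
            assert df.loc[muni, "record_count"] == truth.municipality_records[muni]
        assert df["record_count"].sum() == len(accepted)
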