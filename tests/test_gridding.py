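"""Grid-cell assignment, the ethnomedicinal index, and cell aggregation."""

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ethnogrid.errors import ValidationError
from ethnogrid.gridding import (
    GridSpec,
    aggregate_cells,
    cell_bounds,
    cell_of,
    cells_to_dataframe,
    cells_to_geojson,
    ethnomedicinal_index,
)

from conftest import brute_force_cells, make_enriched

CLASS_POOL = ["CIPD", "DS", "DGS", "NEC", "CBS", "DRS", "PCP", "DGUS", "IPEC"]


def random_records(rng, n_records, n_species=12, span=0.5):
    """Random enriched occurrences in a small window for oracle tests."""
    pool = {}
    for s in range(n_species):
        k = rng.randint(1, len(CLASS_POOL))
        pool[f"Species sp{s}"] = frozenset(rng.sample(CLASS_POOL, k))
    out = []
    for r in range(n_records):
        name = rng.choice(list(pool))
        out.append(
            make_enriched(
                name,
                -99.0 + rng.random() * span,
                21.0 + rng.random() * span,
                pool[name],
                record_id=str(r),
            )
        )
    return out


class TestCellOf:
    @pytest.mark.parametrize(
        "lon, lat, expected",
        [
            (0.0, 0.0, (0, 0)),
            (-98.9999, 21.0001, (-2200, 466)),
            (0.045, 0.045, (1, 1)),  # shared edge belongs to the next cell
            (0.0449999, 0.0449999, (0, 0)),
        ],
    )
    def test_examples(self, lon, lat, expected):
        assert cell_of(lon, lat, GridSpec()) == expected

    def test_custom_origin_shifts_assignment(self):
        spec = GridSpec(cell_size=0.045, origin_lon=-99.2, origin_lat=20.8)
        assert cell_of(-99.2, 20.8, spec) == (0, 0)

    @given(
        st.floats(-179.9, 179.9), st.floats(-89.9, 89.9),
        st.floats(0.01, 1.0),
    )
    def test_point_falls_inside_its_cell_bounds(self, lon, lat, size):
        spec = GridSpec(cell_size=size)
        idx = cell_of(lon, lat, spec)
        west, south, east, north = cell_bounds(idx, spec)
        assert west <= lon and south <= lat
        # floating division can land exactly on the east/north edge only
        # within one ulp; the half-open invariant holds for the index rule
        assert lon < east or math.isclose(lon, east)
        assert lat < north or math.isclose(lat, north)

    def test_invalid_cell_size_rejected(self):
        with pytest.raises(ValidationError):
            GridSpec(cell_size=0.0)


class TestEthnomedicinalIndex:
    def test_worked_values(self):
        assert ethnomedicinal_index([], 19) == 0.0
        assert ethnomedicinal_index([19], 19) == 1.0
        assert ethnomedicinal_index([2, 5, 19], 19) == pytest.approx(26 / 19, abs=1e-12)

    def test_counts_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            ethnomedicinal_index([0], 19)
        with pytest.raises(ValidationError):
            ethnomedicinal_index([20], 19)
        with pytest.raises(ValidationError):
            ethnomedicinal_index([1], 0)

    @given(st.lists(st.integers(1, 19), max_size=50))
    def test_bounds_richness_over_n_to_richness(self, counts):
        ei = ethnomedicinal_index(counts, 19)
        assert len(counts) / 19 <= ei <= len(counts) + 1e-12


class TestAggregateCells:
    def test_unique_species_rule(self):
        recs = [
            make_enriched("Croton cortesianus", -98.95, 21.65,
                          {"DS", "DGS", "CBS", "NEC"}, str(k))
            for k in range(3)
        ]
        cells = aggregate_cells(recs)
        (cell,) = cells.values()
        assert cell.richness == 1
        assert cell.record_count == 3
        assert cell.class_coverage == 4
        assert cell.ei == pytest.approx(4 / 19)

    def test_class_union_and_ei_by_hand(self):
        recs = [
            make_enriched("Aa aa", -98.95, 21.65, {"DS"}, "1"),
            make_enriched("Bb bb", -98.95, 21.65, {"DS", "CBS"}, "2"),
        ]
        (cell,) = aggregate_cells(recs).values()
        assert cell.richness == 2
        assert cell.class_coverage == 2
        assert cell.ei == pytest.approx(3 / 19)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = random.Random(20240917)
        spec = GridSpec()
        for _ in range(50):
            recs = random_records(rng, rng.randint(1, 200))
            mine = aggregate_cells(recs, spec)
            oracle = brute_force_cells(recs, spec)
            assert set(mine) == set(oracle)
            for idx, expect in oracle.items():
                got = mine[idx]
                assert got.richness == expect["richness"]
                assert got.record_count == expect["record_count"]
                assert got.class_coverage == expect["class_coverage"]
                assert got.species == expect["species"]
                assert got.ei == pytest.approx(expect["ei"], abs=1e-12)

    def test_record_order_invariance(self):
        rng = random.Random(7)
        recs = random_records(rng, 120)
        shuffled = recs[:]
        rng.shuffle(shuffled)
        a, b = aggregate_cells(recs), aggregate_cells(shuffled)
        assert set(a) == set(b)
        for idx in a:
            assert (a[idx].richness, a[idx].record_count, a[idx].species,
                    a[idx].class_union, a[idx].ei) == (
                b[idx].richness, b[idx].record_count, b[idx].species,
                b[idx].class_union, b[idx].ei)

    def test_adding_new_species_strictly_increases_richness_and_ei(self):
        base = [make_enriched("Aa aa", -98.95, 21.65, {"DS"}, "1")]
        (before,) = aggregate_cells(base).values()
        extra = base + [make_enriched("Bb bb", -98.951, 21.651, {"DS", "CBS"}, "2")]
        (after,) = aggregate_cells(extra).values()
        assert after.richness == before.richness + 1
        assert after.ei > before.ei
        assert after.class_coverage >= before.class_coverage

    def test_record_counts_sum_to_input(self):
        rng = random.Random(99)
        recs = random_records(rng, 150)
        cells = aggregate_cells(recs)
        assert sum(c.record_count for c in cells.values()) == len(recs)
        assert all(c.richness >= 1 for c in cells.values())

    def test_empty_input_emits_no_cells(self):
        assert aggregate_cells([]) == {}


class TestExports:
    def test_dataframe_columns_and_sorting(self):
        rng = random.Random(3)
        df = cells_to_dataframe(aggregate_cells(random_records(rng, 60)))
        assert list(df.columns) == [
            "i", "j", "west", "south", "east", "north",
            "richness", "record_count", "class_coverage", "ei",
        ]
        keys = list(zip(df["j"], df["i"]))
        assert keys == sorted(keys)

    def test_geojson_rings_closed_and_ccw(self):
        rng = random.Random(3)
        gj = cells_to_geojson(aggregate_cells(random_records(rng, 30)))
        assert gj["type"] == "FeatureCollection"
        for feat in gj["features"]:
            ring = feat["geometry"]["coordinates"][0]
            assert ring[0] == ring[-1] and len(ring) == 5
            area2 = sum(
                ring[k][0] * ring[k + 1][1] - ring[k + 1][0] * ring[k][1]
                for k in range(4)
            )
            assert area2 > 0  # counter-clockwise shoelace
            props = feat["properties"]
            assert {"i", "j", "richness", "record_count",
                    "class_coverage", "ei"} <= set(props)
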