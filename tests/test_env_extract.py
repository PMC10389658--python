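"""Station pooling, zonal statistics (with brute-force oracle), naming."""

import numpy as np
import pytest
from shapely.geometry import Point, box

from lingscape.env_extract import (
    ExtractionConfig,
    RasterGrid,
    StationRecord,
    assemble_master_table,
    filter_station_years,
    name_variable,
    parse_variable,
    read_ascii_grid,
    read_station_csv,
    summarize_environment,
    summarize_stations,
    write_ascii_grid,
    write_station_csv,
    zonal_categorical,
    zonal_numeric,
)
from lingscape.errors import ValidationError
from lingscape.sampling_regions import SamplingRegion


def region_from(geom, lang_id="L1"):
    return SamplingRegion(
        language_id=lang_id, polygon=geom, base_buffer_area=1.0,
        clipped_buffer_area=1.0, region_area=1.0,
    )


def brute_force_zonal(region, raster):
    """Independent per-cell loop: center-in-polygon with scalar shapely."""
    values, nulls = [], 0
    for row in range(raster.n_rows):
        for col in range(raster.n_cols):
            lon = raster.xll + (col + 0.5) * raster.cell_size
            lat = raster.yll + (raster.n_rows - row - 0.5) * raster.cell_size
            if region.polygon.contains(Point(lon, lat)):
                v = raster.values[row, col]
                if v == raster.nodata:
                    nulls += 1
                else:
                    values.append(float(v))
    return values, nulls


class TestStationSummaries:
    def stations(self):
        return [
            StationRecord("s1", 1.0, 1.0, 1960, tavg=10.0),
            StationRecord("s2", 1.5, 1.2, 1961, tavg=20.0),
            StationRecord("s3", 1.2, 0.8, 1962, tavg=30.0),
            StationRecord("s4", 50.0, 50.0, 1960, tavg=-99.0),  # outside
        ]

    def test_mean_and_n(self):
        region = region_from(box(0, 0, 2, 2))
        out = summarize_stations(region, self.stations())
        assert out["tavg"] == (20.0, 3)
        assert out["prcp"][1] == 0 and np.isnan(out["prcp"][0])

    def test_empty_catchment(self):
        region = region_from(box(100, 10, 110, 20))
        out = summarize_stations(region, self.stations())
        assert all(n == 0 for _, n in out.values())

    def test_grand_mean_pools_station_years(self):
        """Mean pools all annual values, not a mean of station means."""
        records = [
            StationRecord("a", 1, 1, 1950 + y, tavg=v)
            for y, v in enumerate([0.0] * 5)
        ] + [StationRecord("b", 1.5, 1.5, 1950, tavg=10.0)]
        region = region_from(box(0, 0, 2, 2))
        mean, n = summarize_stations(region, records)["tavg"]
        assert n == 6
        assert mean == pytest.approx(10.0 / 6)  # not (0 + 10)/2

    def test_region_independence_no_double_count(self):
        """Disjoint regions never share a station-year."""
        records = self.stations()
        r1 = region_from(box(0, 0, 1.1, 2))
        r2 = region_from(box(1.1, 0, 2, 2))
        n1 = summarize_stations(r1, records)["tavg"][1]
        n2 = summarize_stations(r2, records)["tavg"][1]
        assert n1 + n2 == 3


class TestYearWindow:
    def records(self, years):
        return [StationRecord("s", 0, 0, y, tavg=1.0) for y in years]

    def test_inclusive_bounds(self):
        kept = filter_station_years(self.records([1950, 1951, 1980, 1981]),
                                    (1951, 1980))
        assert [r.year for r in kept] == [1951, 1980]

    def test_empty_input(self):
        assert filter_station_years([], (1951, 1980)) == []

    def test_widening_never_decreases_n(self):
        records = self.records(range(1940, 1995))
        narrow = len(filter_station_years(records, (1951, 1980)))
        wide = len(filter_station_years(records, (1945, 1985)))
        assert wide >= narrow

    def test_inverted_window_rejected(self):
        with pytest.raises(ValidationError):
            filter_station_years([], (1980, 1951))
        with pytest.raises(ValidationError):
            ExtractionConfig(station_window=(1980, 1951))


class TestZonalNumeric:
    def test_constant_field(self):
        grid = RasterGrid(0, 0, 1.0, np.full((4, 4), 5.0))
        region = region_from(box(0.2, 0.2, 3.8, 3.8))
        stats = zonal_numeric(region, grid)
        assert stats["average"] == stats["median"] == 5.0
        assert stats["std_dev"] == 0.0 and stats["range"] == 0.0

    def test_two_by_two_hand_computed(self):
        grid = RasterGrid(0, 0, 1.0, np.array([[1.0, 2.0], [3.0, 4.0]]))
        region = region_from(box(-1, -1, 3, 3))
        stats = zonal_numeric(region, grid)
        assert stats["n"] == 4
        assert stats["average"] == 2.5
        assert stats["median"] == 2.5
        assert stats["variance"] == pytest.approx(5 / 3)  # sample variance
        assert stats["range"] == 3.0
        assert stats["first_quartile"] == pytest.approx(1.75)  # type 7
        assert stats["third_quartile"] == pytest.approx(3.25)

    def test_nodata_counted_and_excluded(self):
        values = np.array([[1.0, -9999.0], [-9999.0, -9999.0]])
        grid = RasterGrid(0, 0, 1.0, values)
        region = region_from(box(-1, -1, 3, 3))
        stats = zonal_numeric(region, grid)
        assert stats["null_cells"] == 3
        assert stats["n"] == 1 and stats["average"] == 1.0

    def test_zero_cells_absent_stats(self):
        grid = RasterGrid(0, 0, 1.0, np.ones((3, 3)))
        region = region_from(box(50, 50, 51, 51))
        stats = zonal_numeric(region, grid)
        assert stats["n"] == 0
        assert np.isnan(stats["average"])

    def test_matches_brute_force_oracle(self, rng):
        """Random region/raster pairs agree exactly with a per-cell loop."""
        for _ in range(20):
            n = int(rng.integers(10, 30))
            values = rng.normal(size=(n, n)).round(3)
            values[rng.random((n, n)) < 0.05] = -9999.0
            grid = RasterGrid(
                xll=float(rng.uniform(-10, 10)),
                yll=float(rng.uniform(-10, 10)),
                cell_size=float(rng.uniform(0.2, 1.0)),
                values=values,
            )
            cx = grid.xll + grid.n_cols * grid.cell_size * rng.uniform(0.2, 0.8)
            cy = grid.yll + grid.n_rows * grid.cell_size * rng.uniform(0.2, 0.8)
            region = region_from(
                Point(cx, cy).buffer(
                    grid.cell_size * rng.uniform(2, 8), quad_segs=4
                )
            )
            expected, nulls = brute_force_zonal(region, grid)
            stats = zonal_numeric(region, grid)
            assert stats["n"] == len(expected)
            assert stats["null_cells"] == nulls
            if expected:
                assert stats["average"] == pytest.approx(np.mean(expected),
                                                         abs=1e-9)
                assert stats["median"] == pytest.approx(np.median(expected),
                                                        abs=1e-9)


class TestZonalCategorical:
    def grid(self, values):
        return RasterGrid(0, 0, 1.0, np.asarray(values, dtype=int),
                          kind="categorical")

    CLASSES = {0: "water", 1: "short", 2: "med", 3: "tall", 4: "snow"}

    def test_single_class(self):
        grid = self.grid(np.zeros((2, 5), dtype=int))
        counts = zonal_categorical(region_from(box(-1, -1, 6, 3)), grid,
                                   self.CLASSES)
        assert counts["water"] == 10
        assert counts["tall"] == 0

    def test_counts_conserve_cell_total(self):
        values = np.array([[1, 1, 1], [2, 2, 1], [1, 2, 1]])
        grid = self.grid(values)
        region = region_from(box(-1, -1, 4, 4))
        counts = zonal_categorical(region, grid, self.CLASSES)
        assert counts["short"] == 6 and counts["med"] == 3
        stats_n = zonal_numeric(
            region, RasterGrid(0, 0, 1.0, values.astype(float))
        )["n"]
        assert sum(counts.values()) == stats_n

    def test_off_raster_region_warns(self):
        grid = self.grid(np.zeros((2, 2), dtype=int))
        with pytest.warns(UserWarning, match="no raster cells"):
            counts = zonal_categorical(region_from(box(50, 50, 51, 51)), grid,
                                       self.CLASSES)
        assert all(v == 0 for v in counts.values())

    def test_unknown_code_flagged(self):
        grid = self.grid(np.full((2, 2), 9, dtype=int))
        with pytest.warns(UserWarning, match="class_map"):
            zonal_categorical(region_from(box(-1, -1, 3, 3)), grid, self.CLASSES)


class TestNaming:
    @pytest.mark.parametrize(
        "parts, expected",
        [
            (("tavg", "dC", "avg"), "v_tavg_dC__avg"),
            (("elev", "m", "median"), "v_elev_m__median"),
            (("lc_tall", "ct", "sum"), "v_lc_tall_ct__sum"),
            (("elev", "m", "std_dev"), "v_elev_m__std_dev"),
        ],
    )
    def test_compose_and_parse(self, parts, expected):
        assert name_variable(*parts) == expected
        assert parse_variable(expected) == parts

    @pytest.mark.parametrize(
        "parts", [("", "m", "avg"), ("t avg", "dC", "avg"), ("t", "d_C", "avg"),
                  ("t", "dC", "a__vg")],
    )
    def test_bad_components_rejected(self, parts):
        with pytest.raises(ValidationError):
            name_variable(*parts)


class TestAsciiGridIO:
    def test_numeric_round_trip(self, tmp_path, rng):
        grid = RasterGrid(-3.5, 10.0, 0.25, rng.normal(size=(6, 9)))
        path = tmp_path / "g.asc"
        write_ascii_grid(grid, path)
        loaded = read_ascii_grid(path)
        assert loaded.xll == grid.xll and loaded.cell_size == grid.cell_size
        np.testing.assert_allclose(loaded.values, grid.values, atol=1e-9)

    def test_categorical_round_trip(self, tmp_path):
        grid = RasterGrid(0, 0, 1.0, np.arange(6).reshape(2, 3),
                          kind="categorical")
        path = tmp_path / "g.asc"
        write_ascii_grid(grid, path)
        loaded = read_ascii_grid(path, kind="categorical")
        np.testing.assert_array_equal(loaded.values, grid.values)


class TestStationCsvIO:
    def test_round_trip_with_missing(self, tmp_path):
        records = [
            StationRecord("s1", 0.0, 1.0, 1955, tavg=3.25, prcp=812.0),
            StationRecord("s2", -5.0, 2.0, 1956, tmin=-4.0),
        ]
        path = tmp_path / "stations.csv"
        write_station_csv(records, path)
        loaded = read_station_csv(path)
        assert loaded == records


class TestMasterTable:
    @staticmethod
    def make_record(**overrides):
        from lingscape.language_table import LanguageRecord

        kwargs = dict(
            id="x1", name="Example", lon=10.0, lat=-5.0, stable=True,
            onset=2, coda=1, vq=5, vtotal=9, ctotal=22, obstr=15,
            tone_cat="Simple", n_ejectives=2, glot_c="Ej", vow_index=0.41,
        )
        kwargs.update(overrides)
        return LanguageRecord(**kwargs)

    def test_assembly_shape_and_missing(self, tmp_path):
        from lingscape.env_extract import EnvSummary

        make_record = self.make_record
        records = [make_record(id=f"x{i}", lon=float(i)) for i in range(3)]
        regions = [region_from(box(0, 0, 1, 1), lang_id="x0"),
                   region_from(box(1, 0, 2, 1), lang_id="x1")]
        summaries = [
            EnvSummary("x0", {"v_tavg_dC__avg": 21.0, "v_elev_m__median": 100.0}),
            EnvSummary("x1", {"v_tavg_dC__avg": 12.0}),
        ]
        master = assemble_master_table(records, regions, summaries)
        assert len(master) == 3
        assert master.loc[2, "id"] == "x2"
        assert np.isnan(master.loc[2, "v_tavg_dC__avg"])
        assert np.isnan(master.loc[1, "v_elev_m__median"])
        assert master.loc[0, "v_tavg_dC__avg"] == 21.0

        path = tmp_path / "master.csv"
        master.to_csv(path, index=False)
        import pandas as pd

        loaded = pd.read_csv(path, dtype={"id": str})
        np.testing.assert_allclose(
            loaded["v_tavg_dC__avg"].to_numpy(dtype=float),
            master["v_tavg_dC__avg"].to_numpy(dtype=float),
            atol=1e-9,
        )


def test_summarize_environment_names(small_world):
    from lingscape.sampling_regions import build_regions

    region = build_regions(small_world.languages[:3], small_world.coastline)[0]
    summary = summarize_environment(
        region,
        stations=small_world.stations[:2000],
        numeric_rasters={"elev": (small_world.rasters["elev"], "m")},
        landcover=(small_world.rasters["landcover"],
                   small_world.landcover_classes),
    )
    for name in summary.variables:
        parse_variable(name)
    assert "v_tavg_dC__avg" in summary.variables
    assert "v_elev_m__median" in summary.variables
    assert "v_lc_water_ct__sum" in summary.variables
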