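"""Core types, the default attribute table, I/O round-trips and summaries."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import shapely

import ediblecity as ec
from ediblecity.core import CITY_COLUMNS

from conftest import CRS, make_city, square

DATA = Path(__file__).parent / "data"


class TestAttributeTable:
    def test_default_matches_reference_matrix(self):
        """The built-in table reproduces the published per-land-use
        parameter matrix (checked-in CSV oracle)."""
        ref = pd.read_csv(DATA / "table2.csv").set_index("land_use")
        got = ec.default_attribute_table().df[ref.columns]
        pd.testing.assert_frame_equal(
            got.astype(float), ref.astype(float), check_like=True
        )

    @pytest.mark.parametrize(
        "land_use, col, value",
        [
            ("Hydroponic rooftop", "food1", 9.0),
            ("Hydroponic rooftop", "food2", 19.0),
            ("Hydroponic rooftop", "CN1", 98),
            ("Trees", "no2_seq1", 0.11),
            ("Trees", "pGreen", 1.0),
            ("Edible private garden", "pGreen", 0.6),
            ("Edible private garden", "CN1", 85),
            ("Edible private garden", "CN2", 88),
        ],
    )
    def test_printed_values(self, land_use, col, value):
        df = ec.default_attribute_table().df
        assert df.loc[land_use, col] == value

    def test_flags(self):
        t = ec.default_attribute_table()
        assert set(t.flagged("edible")) == {
            "Edible private garden", "Community garden", "Commercial garden",
            "Rooftop garden", "Hydroponic rooftop",
        }
        assert "Community garden" in t.flagged("public")
        assert "Normal garden" in t.flagged("private")
        assert "Raised bed" in t.flagged("harvest")

    def test_csv_round_trip(self, tmp_path):
        t = ec.urban_attribute_table()
        p = tmp_path / "attrs.csv"
        ec.write_attribute_table(t, p)
        back = ec.read_attribute_table(p)
        pd.testing.assert_frame_equal(back.df, t.df, check_dtype=False)

    def test_invalid_table_rejected(self):
        df = ec.default_attribute_table().df.reset_index()
        df.loc[0, "CN1"] = 0
        with pytest.raises(ec.SchemaError):
            ec.AttributeTable(df)

    def test_unknown_land_use_is_listed(self, table):
        with pytest.raises(ec.SchemaError, match="Space elevator"):
            table.check_covers(["Grass", "Space elevator"])


class TestCityIO:
    def _city12(self):
        rows = [
            dict(geometry=square(i * 30, j * 30, 20),
                 land_use=["Grass", "Rooftop", "Vacant"][(i + j) % 3],
                 land_use_verbose="Residence" if (i + j) % 3 == 1 else "x",
                 floors=3 if (i + j) % 3 == 1 else 0,
                 edible_area=5.0 * i)
            for i in range(4) for j in range(3)
        ]
        return make_city(rows)

    def test_round_trip_identity(self, tmp_path):
        city = self._city12()
        p = tmp_path / "city.geojson"
        ec.write_city(city, p)
        back = ec.read_city(p)
        assert len(back) == 12
        assert back.crs == city.crs
        for col in CITY_COLUMNS:
            if col in ("area", "flat_area", "edible_area"):
                np.testing.assert_allclose(
                    back.df[col].to_numpy(), city.df[col].to_numpy(),
                    atol=1e-6)
            else:
                assert (back.df[col] == city.df[col]).all()
        for g1, g2 in zip(back.geometry, city.geometry):
            assert g1.equals_exact(g2, tolerance=1e-6)

    def test_missing_mandatory_column_named(self, tmp_path):
        city = self._city12()
        df = city.df.drop(columns=["land_use"])
        from ediblecity.core import _write_features

        p = tmp_path / "bad.geojson"
        _write_features(df, city.crs, p)
        with pytest.raises(ec.SchemaError, match="land_use"):
            ec.read_city(p)

    def test_optional_columns_filled(self, tmp_path):
        city = self._city12()
        df = city.df.drop(columns=["edible_area", "flat_area"])
        from ediblecity.core import _write_features

        p = tmp_path / "partial.geojson"
        _write_features(df, city.crs, p)
        back = ec.read_city(p)
        assert (back.df["edible_area"] == 0).all()
        assert (back.df["flat_area"] == back.df["area"]).all()

    def test_geographic_crs_rejected(self, tmp_path):
        city = self._city12()
        from ediblecity.core import _write_features

        p = tmp_path / "geo.geojson"
        _write_features(city.df, "EPSG:4326", p)
        with pytest.raises(ec.CRSError):
            ec.read_city(p)

    def test_empty_city_round_trip(self, tmp_path):
        empty = ec.CityModel(
            pd.DataFrame(columns=list(CITY_COLUMNS) + ["geometry"]), CRS)
        p = tmp_path / "empty.geojson"
        ec.write_city(empty, p)
        assert len(ec.read_city(p)) == 0

    def test_overwrite(self, tmp_path):
        p = tmp_path / "c.geojson"
        ec.write_city(self._city12(), p)
        small = make_city([dict(geometry=square(0, 0, 10),
                                land_use="Grass")])
        ec.write_city(small, p)
        assert len(ec.read_city(p)) == 1

    def test_invariant_violations_rejected(self):
        with pytest.raises(ec.SchemaError, match="floors"):
            make_city([dict(geometry=square(0, 0, 10), land_use="Grass",
                            floors=-1)])
        with pytest.raises(ec.SchemaError, match="edible_area"):
            make_city([dict(geometry=square(0, 0, 10), land_use="Grass",
                            edible_area=200.0)])

    def test_area_mismatch_warns(self):
        with pytest.warns(UserWarning, match="declared area"):
            make_city([dict(geometry=square(0, 0, 10), land_use="Grass",
                            area=300.0, flat_area=100.0)])


class TestSvfIO:
    @pytest.mark.parametrize("ext", ["tif", "asc"])
    def test_round_trip(self, tmp_path, ext):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 1, (50, 50))
        values[0, 0] = np.nan
        grid = ec.SvfGrid(values, 1000.0, 2000.0, 5.0, CRS)
        p = tmp_path / f"svf.{ext}"
        ec.write_svf(grid, p)
        back = ec.read_svf(p)
        assert back.shape == (50, 50)
        assert back.cell_size == 5.0
        assert back.x_origin == 1000.0 and back.y_origin == 2000.0
        np.testing.assert_allclose(back.values, values, atol=1e-6)
        assert np.isnan(back.values[0, 0])

    def test_constant_grid(self, tmp_path, flat_svf):
        p = tmp_path / "svf.tif"
        ec.write_svf(flat_svf, p)
        assert np.allclose(ec.read_svf(p).values, 0.8, atol=1e-7)

    def test_out_of_range_rejected(self, tmp_path):
        grid = ec.SvfGrid(np.full((20, 20), 7.5), 0.0, 200.0, 10.0, CRS)
        p = tmp_path / "bad.asc"
        ec.write_svf(grid, p)
        with pytest.raises(ValueError, match="outside"):
            ec.read_svf(p)

    def test_multiband_rejected(self, tmp_path):
        import tifffile

        p = tmp_path / "multi.tif"
        tifffile.imwrite(p, np.zeros((3, 10, 10), dtype=np.float32),
                         photometric="minisblack")
        with pytest.raises(ValueError):
            ec.read_svf(p)


class TestSummarize:
    def test_constant(self):
        s = ec.summarize([5, 5, 5])
        assert s == (5, 5, 5, 5, 5, 5)

    def test_four_values(self):
        s = ec.summarize([1, 2, 3, 4])
        assert s.min == 1 and s.max == 4
        assert s.median == 2.5 and s.mean == 2.5

    def test_uniform_draws(self):
        rng = np.random.default_rng(11)
        s = ec.summarize(rng.uniform(0, 1, 1000))
        expected = (0, 0.25, 0.5, 0.5, 0.75, 1)
        for got, want in zip(s, expected):
            assert abs(got - want) < 0.05

    def test_matches_sorting_oracle(self):
        """Quantiles agree with an independent order-statistic
        interpolation on random vectors."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.normal(size=rng.integers(2, 40))
            s = ec.summarize(x)
            xs = np.sort(x)

            def q(p, xs=xs):
                h = (len(xs) - 1) * p
                lo = int(np.floor(h))
                hi = min(lo + 1, len(xs) - 1)
                return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

            assert s.q25 == pytest.approx(q(0.25), rel=1e-12)
            assert s.median == pytest.approx(q(0.5), rel=1e-12)
            assert s.q75 == pytest.approx(q(0.75), rel=1e-12)
            assert s.min <= s.q25 <= s.median <= s.q75 <= s.max
            assert s.min <= s.mean <= s.max

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ec.summarize([])


class TestRandomEngine:
    def test_substreams_reproducible_and_independent(self):
        a1 = ec.substream(42, "runoff").uniform(size=5)
        a2 = ec.substream(42, "runoff").uniform(size=5)
        b = ec.substream(42, "food").uniform(size=5)
        np.testing.assert_array_equal(a1, a2)
        assert not np.allclose(a1, b)
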