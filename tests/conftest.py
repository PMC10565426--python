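import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from ediblecity import CityModel, SvfGrid, generate_city, urban_attribute_table

CRS = "EPSG:25831"


def make_city(rows, crs=CRS):
    """Build a CityModel from dicts of (geometry, land_use, ...); area
    attributes default to the polygon area."""
    records = []
    for r in rows:
        geom = r["geometry"]
        rec = dict(
            land_use=r["land_use"],
            land_use_verbose=r.get("land_use_verbose", r["land_use"]),
            floors=int(r.get("floors", 0)),
            area=float(r.get("area", geom.area)),
            flat_area=float(r.get("flat_area", r.get("area", geom.area))),
            edible_area=float(r.get("edible_area", 0.0)),
            geometry=geom,
        )
        records.append(rec)
    df = pd.DataFrame(records)
    df.index.name = "id"
    return CityModel(df, crs)


def square(x, y, side):
    return box(x, y, x + side, y + side)


@pytest.fixture(scope="session")
def table():
    return urban_attribute_table()


@pytest.fixture(scope="session")
def city():
    """The default synthetic fixture city (~220 elements)."""
    return generate_city()


@pytest.fixture
def flat_svf():
    """Constant-0.8 grid covering x,y in [0, 500]^2."""
    return SvfGrid(np.full((50, 50), 0.8), 0.0, 500.0, 10.0, CRS)
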