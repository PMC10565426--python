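"""Runoff prevention with rainwater harvesting.

SCS curve-number runoff for a 24-hour design storm, with the initial
abstraction augmented by rainwater harvested from adjacent higher roofs:

    S  = 25400 / CN - 254                       (potential retention, mm)
    Ia = 0.2 S + min{Rh, Ws} / area             (initial abstraction, mm)
    Q  = 0                     if P <= Ia
         (P - Ia)^2 / ((P - Ia) + S)            otherwise

Per element, the curve number is drawn uniformly from its land-use range
[CN1, CN2].  Rh is the rain falling on adjacent (within ``harvest_dist``
metres) non-edible surfaces with strictly more floors, each such surface
crediting only its nearest harvester (1 mm on 1 m2 = 1 L); Ws is a tank
capacity drawn per element from ``tank_size`` litres per m2 of surface.
The city-scale figure is the area-weighted mean of per-element runoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .core import AttributeTable, CityModel, make_rng

__all__ = [
    "RunoffParams",
    "RunoffResult",
    "potential_retention",
    "harvest_terms",
    "runoff_prev",
]


@dataclass
class RunoffParams:
    """Design-storm and harvesting parameters.

    rain: storm depth over 24 h (mm); floors_field: attribute holding the
    number of floors; harvest_dist: maximum distance for a roof to count
    as adjacent (m); tank_size: [lo, hi] tank volume per m2 of element
    surface (L/m2).
    """

    rain: float = 85.0
    floors_field: str = "floors"
    harvest_dist: float = 10.0
    tank_size: tuple[float, float] = (0.0, 45.0)

    def __post_init__(self) -> None:
        if self.rain < 0:
            raise ValueError("rain must be >= 0")
        if self.harvest_dist < 0:
            raise ValueError("harvest_dist must be >= 0")
        lo, hi = self.tank_size
        if not 0 <= lo <= hi:
            raise ValueError("tank_size must satisfy 0 <= lo <= hi")


@dataclass
class RunoffResult:
    """City-scale outcome: runoff depth (mm), total rainfall and total
    rainwater harvested (m3)."""

    runoff: float
    rainfall: float
    rainharvest: float


def potential_retention(cn):
    """Potential soil-moisture retention S (mm) from the curve number,
    metric form S = 25400/CN - 254.  Accepts scalars or arrays."""
    cn = np.asarray(cn, dtype=float)
    if np.any((cn <= 0) | (cn > 100)):
        raise ValueError("curve numbers must lie in (0, 100]")
    s = 25400.0 / cn - 254.0
    return float(s) if s.ndim == 0 else s


def harvest_terms(
    city: CityModel,
    table: AttributeTable,
    params: RunoffParams | None = None,
    rng: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element potential harvest Rh and tank capacity Ws (litres).

    Catchments for a harvest-capable element are the non-edible elements
    within ``harvest_dist`` of its boundary with strictly more floors;
    each catchment surface is credited to its nearest harvester only, so
    the same rain is never counted twice.  Non-harvesting elements get
    (0, 0).
    """
    params = params if params is not None else RunoffParams()
    rng = make_rng(rng)
    n = len(city)
    rh = np.zeros(n)
    ws = np.zeros(n)
    if n == 0:
        return rh, ws
    land_uses = city.df["land_use"].tolist()
    table.check_covers(land_uses)
    can_harvest = table.col("harvest", land_uses).astype(bool)
    is_edible = table.col("edible", land_uses).astype(bool)
    floors = city.df[params.floors_field].to_numpy()
    geoms = city.geometry
    areas = city.df["area"].to_numpy()

    lo, hi = params.tank_size
    draws = rng.uniform(lo, hi, size=n)
    ws[can_harvest] = draws[can_harvest] * areas[can_harvest]

    harvester_idx = np.flatnonzero(can_harvest)
    if harvester_idx.size:
        tree = shapely.STRtree(geoms[harvester_idx])
        cand_idx = np.flatnonzero(~is_edible)
        if cand_idx.size:
            qi, ti = tree.query(
                geoms[cand_idx], predicate="dwithin",
                distance=params.harvest_dist,
            )
            ci = cand_idx[qi]          # catchment element index
            hi_ = harvester_idx[ti]    # harvester element index
            keep = floors[ci] > floors[hi_]
            ci, hi_ = ci[keep], hi_[keep]
            if ci.size:
                dist = shapely.distance(geoms[ci], geoms[hi_])
                pairs = pd.DataFrame({"c": ci, "h": hi_, "d": dist})
                # nearest harvester wins each catchment (ties: lowest index)
                pairs = pairs.sort_values(["c", "d", "h"], kind="stable")
                nearest = pairs.groupby("c", sort=True).first()
                for c, row in nearest.iterrows():
                    rh[int(row["h"])] += params.rain * areas[int(c)]
    return rh, ws


def runoff_prev(
    city: CityModel,
    table: AttributeTable,
    params: RunoffParams | None = None,
    rng: int | np.random.Generator | None = None,
    detailed: bool = False,
):
    """City-scale runoff, rainfall and rainwater harvested.

    Returns a :class:`RunoffResult`; with ``detailed=True`` also a
    per-element DataFrame of the hydrological terms (CN, S, Rh, Ws, Ia, Q).
    """
    params = params if params is not None else RunoffParams()
    rng = make_rng(rng)
    df = city.df
    n = len(df)
    if n == 0:
        result = RunoffResult(0.0, 0.0, 0.0)
        if detailed:
            return result, pd.DataFrame(
                columns=["CN", "S", "Rh", "Ws", "Ia", "Q"])
        return result
    land_uses = df["land_use"].tolist()
    cn1 = table.col("CN1", land_uses).astype(float)
    cn2 = table.col("CN2", land_uses).astype(float)

    rh, ws = harvest_terms(city, table, params, rng)

    cn = rng.uniform(cn1, cn2)
    s = potential_retention(cn)
    areas = df["area"].to_numpy()
    harvested = np.minimum(rh, ws)          # litres actually captured
    ia = 0.2 * s + harvested / areas        # 1 L/m2 = 1 mm
    p = params.rain
    excess = p - ia
    q = np.where(excess > 0, excess**2 / (excess + s), 0.0)

    total_area = areas.sum()
    result = RunoffResult(
        runoff=float((q * areas).sum() / total_area),
        rainfall=float(p * total_area / 1000.0),
        rainharvest=float(harvested.sum() / 1000.0),
    )
    if detailed:
        detail = pd.DataFrame(
            {"CN": cn, "S": s, "Rh": rh, "Ws": ws, "Ia": ia, "Q": q},
            index=df.index,
        )
        return result, detail
    return result
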