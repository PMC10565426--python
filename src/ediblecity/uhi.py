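"""Urban heat island indicator.

Diagnoses the air-temperature excess of the urban street canyon over the
rural surroundings per raster cell, from the sky view factor SVF and the
vegetated fraction Fveg of the cell:

    UHI_i = (2 - SVF_i - Fveg_i) * (Qql * dT^3 / (Cair * Pair * U))^(1/4)

with dT = Tmax - Tmin.  Default meteorology is a Western-Mediterranean
summer day.  Fveg is rasterized from the city polygons: each cell takes
the green fraction (pGreen) of the polygon containing its centre; for
urban-agriculture elements the element-level ratio edible_area/area
overrides the land-use default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .core import AttributeTable, CityModel, SummaryStats, SvfGrid, summarize

__all__ = ["UhiParams", "rasterize_fveg", "uhi", "uhi_magnitude"]


@dataclass
class UhiParams:
    """Meteorological drivers of the heat-island diagnostic.

    Qql: daily average global radiation (W/m2/hour); Cair: air heat
    capacity (J/kg/K); Pair: air density (kg/m3); Tmax/Tmin: daily
    average max/min temperature (degC); windspeed: daily average (m/s).
    """

    Qql: float = 6.11
    Cair: float = 1007.0
    Pair: float = 1.14
    Tmax: float = 30.8
    Tmin: float = 20.0
    windspeed: float = 2.77

    def __post_init__(self) -> None:
        if self.Tmax < self.Tmin:
            raise ValueError("Tmax must be >= Tmin")
        if min(self.Qql, self.Cair, self.Pair, self.windspeed) <= 0:
            raise ValueError("Qql, Cair, Pair and windspeed must be > 0")


def uhi_magnitude(params: UhiParams) -> float:
    """The meteorological factor (Qql * dT^3 / (Cair * Pair * U))^(1/4)."""
    dT = params.Tmax - params.Tmin
    return float(
        (params.Qql * dT**3 / (params.Cair * params.Pair * params.windspeed))
        ** 0.25
    )


def _element_green_fraction(city: CityModel, table: AttributeTable) -> np.ndarray:
    """Per-element vegetated fraction: pGreen of the land use, overridden
    by edible_area/area for urban-agriculture solutions."""
    land_uses = city.df["land_use"].tolist()
    table.check_covers(land_uses)
    pgreen = table.col("pGreen", land_uses).astype(float)
    edible = table.col("edible", land_uses).astype(bool)
    ratio = (city.df["edible_area"] / city.df["area"]).to_numpy()
    return np.where(edible, np.clip(ratio, 0.0, 1.0), pgreen)


def rasterize_fveg(
    city: CityModel, table: AttributeTable, template: SvfGrid
) -> SvfGrid:
    """Vegetation-fraction grid aligned to ``template``.

    Each cell carries the green fraction of the polygon containing its
    centre; cells over no polygon get 0.  City and template must share
    the CRS (reproject upstream otherwise).
    """
    if city.crs != template.crs:
        raise ValueError(
            f"CRS mismatch: city is {city.crs}, raster is {template.crs}; "
            "reproject one of them"
        )
    out = np.zeros(template.shape, dtype=float)
    if len(city) == 0:
        return SvfGrid(out, template.x_origin, template.y_origin,
                       template.cell_size, template.crs)
    fractions = _element_green_fraction(city, table)
    X, Y = template.cell_centers()
    points = shapely.points(X, Y)
    tree = shapely.STRtree(city.geometry)
    pt_idx, poly_idx = tree.query(points, predicate="within")
    # one polygon per cell centre: first match wins on overlaps
    flat = out.ravel()
    seen = np.zeros(flat.size, dtype=bool)
    for pi, gi in zip(pt_idx, poly_idx):
        if not seen[pi]:
            flat[pi] = fractions[gi]
            seen[pi] = True
    return SvfGrid(flat.reshape(template.shape), template.x_origin,
                   template.y_origin, template.cell_size, template.crs)


def uhi(
    city: CityModel,
    svf: SvfGrid,
    table: AttributeTable,
    params: UhiParams | None = None,
    return_raster: bool = False,
    verbose: bool = False,
) -> SummaryStats | SvfGrid | np.ndarray:
    """Urban heat island per cell of the SVF grid (degC).

    Default return is the six-number summary over finite cells;
    ``return_raster`` gives the per-cell grid, ``verbose`` the flat vector
    of finite-cell values.  Negative cell values (vegetation plus sky view
    numerically exceeding 2) are floored at 0; nodata SVF cells are
    excluded.
    """
    params = params if params is not None else UhiParams()
    finite = svf.finite_mask()
    if not finite.any():
        raise ValueError("SVF raster has no finite cells")
    fveg = rasterize_fveg(city, table, svf)
    values = (2.0 - svf.values - fveg.values) * uhi_magnitude(params)
    values = np.where(finite, np.maximum(values, 0.0), np.nan)
    if return_raster:
        return SvfGrid(values, svf.x_origin, svf.y_origin, svf.cell_size,
                       svf.crs)
    flat = values[finite]
    if verbose:
        return flat
    return summarize(flat)
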