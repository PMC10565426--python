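"""Green-area accessibility and green-per-capita equity.

``green_distance`` measures, for each residence, the straight-line
distance to the closest public green area above a minimum size; its
defaults follow the WHO recommendation that every residence be within
300 m of a public green area larger than 0.5 ha.

``green_capita`` yields either the city-level green surface per
inhabitant or, with a neighbourhood layer, the max/min ratio of
neighbourhood-level green per capita (1 = perfect spatial equality;
higher values mean less spatial justice).  Private gardens can be
included to avoid underestimating green in wealthier districts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import shapely

from .core import (
    AttributeTable,
    CityModel,
    NeighbourhoodLayer,
    SummaryStats,
    summarize,
)

__all__ = ["green_distance", "green_capita"]


def _green_mask(
    city: CityModel,
    table: AttributeTable,
    categories: Sequence[str] | None,
    flag: str = "public",
    include_private: bool = False,
) -> np.ndarray:
    land_use = city.df["land_use"]
    if categories is not None:
        return land_use.isin(set(categories)).to_numpy()
    cats = set(table.flagged(flag))
    if include_private:
        cats |= set(table.flagged("private"))
    return land_use.isin(cats).to_numpy()


def green_distance(
    city: CityModel,
    table: AttributeTable,
    green_cat: Sequence[str] | None = None,
    residence_col: str = "land_use_verbose",
    residences: Sequence[str] = ("Residence",),
    min_area: float = 5000.0,
    percent_out: bool = False,
    max_dist: float = 300.0,
    verbose: bool = False,
) -> SummaryStats | float | np.ndarray:
    """Distance from each residence to its closest qualifying green area.

    Qualifying greens are public-flagged land uses (or the explicit
    ``green_cat`` list) with ``area >= min_area``.  Distances are minimum
    boundary-to-boundary Euclidean distances (0 when geometries touch or
    overlap).  Default return is the six-number summary; ``percent_out``
    returns the percentage of residences farther than ``max_dist``;
    ``verbose`` the raw distance vector.
    """
    if isinstance(residences, str):
        residences = (residences,)
    df = city.df
    res_mask = df[residence_col].isin(set(residences)).to_numpy()
    if not res_mask.any():
        raise ValueError(f"no residences found via {residence_col!r}")
    green_mask = _green_mask(city, table, green_cat)
    green_mask &= (df["area"] >= min_area).to_numpy()
    if not green_mask.any():
        raise ValueError(
            f"no qualifying green areas (flagged public, area >= {min_area} "
            "m2); distances are undefined"
        )
    res_geoms = city.geometry[res_mask]
    green_geoms = city.geometry[green_mask]
    tree = shapely.STRtree(green_geoms)
    nearest = tree.query_nearest(res_geoms)
    # query_nearest returns all ties; keep one per residence
    dmat = shapely.distance(res_geoms[nearest[0]], green_geoms[nearest[1]])
    dists = np.full(res_geoms.size, np.inf)
    np.minimum.at(dists, nearest[0], dmat)
    if verbose:
        return dists
    if percent_out:
        return float(100.0 * np.mean(dists > max_dist))
    return summarize(dists)


def green_capita(
    city: CityModel,
    table: AttributeTable,
    green_categories: Sequence[str] | None = None,
    inhabitants: int | None = None,
    neighbourhoods: NeighbourhoodLayer | None = None,
    name_col: str = "name",
    inh_col: str = "inhabitants",
    private: bool = False,
    verbose: bool = False,
    min_inh: int = 0,
):
    """Green surface per inhabitant.

    City mode (``inhabitants`` given): total green area / inhabitants, in
    m2/person.  Neighbourhood mode (``neighbourhoods`` given): green area
    is apportioned to neighbourhoods by geometric intersection, divided by
    each neighbourhood's population; neighbourhoods below ``min_inh``
    inhabitants are dropped and the max/min ratio is returned (or the
    per-neighbourhood values when ``verbose``).
    """
    if (inhabitants is None) == (neighbourhoods is None):
        raise ValueError(
            "provide exactly one of `inhabitants` (city mode) or "
            "`neighbourhoods` (equity mode)"
        )
    mask = _green_mask(city, table, green_categories,
                       include_private=private)
    green_geoms = city.geometry[mask]
    green_areas = city.df["area"].to_numpy()[mask]

    if inhabitants is not None:
        if inhabitants <= 0:
            raise ValueError("inhabitants must be > 0")
        return float(green_areas.sum() / inhabitants)

    ndf = neighbourhoods.df
    keep = ndf[ndf[inh_col] >= min_inh]
    if len(keep) == 0:
        raise ValueError(
            f"all neighbourhoods excluded by min_inh={min_inh}"
        )
    if (keep[inh_col] <= 0).any():
        raise ValueError("an included neighbourhood has zero inhabitants")
    values: dict[str, float] = {}
    for _, row in keep.iterrows():
        poly = row["geometry"]
        if green_geoms.size:
            # apportion straddling elements by intersection area, scaled to
            # the declared (attribute) area of each element
            inter = shapely.area(shapely.intersection(green_geoms, poly))
            geom_area = shapely.area(green_geoms)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(geom_area > 0, inter / geom_area, 0.0)
            g = float((green_areas * frac).sum())
        else:
            g = 0.0
        values[row[name_col]] = g / float(row[inh_col])
    if verbose:
        return values
    vals = np.array(list(values.values()))
    if vals.min() == 0:
        raise ValueError(
            "a neighbourhood has zero green; the max/min ratio is undefined"
        )
    return float(vals.max() / vals.min())
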