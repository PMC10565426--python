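"""Randomized per-element indicators and the shared Monte-Carlo engine.

NO2 sequestration is a single randomized total: per element the capacity
is drawn uniformly from its land-use range and multiplied by the
vegetated area (pGreen * area, overridden by edible_area for
urban-agriculture solutions):  NO2 = sum(a_i * cap_i) / 1000.

Jobs, volunteers and food production are linear per-m2 indicators whose
rate is uncertain; a Monte-Carlo simulation (1,000 iterations by default)
propagates the uniform rate ranges into an empirical confidence interval.
Jobs and volunteers draw one rate per iteration (the same coefficient
applies city-wide); food and NO2 draw independently per element.

Purpose conventions: jobs are created by commercial solutions
(Commercial garden, Hydroponic rooftop); volunteers are involved in
community solutions (Community garden, Rooftop garden); edible private
gardens count for food production only (personal use).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import AttributeTable, CityModel, IntervalEstimate, make_rng

__all__ = [
    "mc_interval",
    "no2_seq",
    "edible_jobs",
    "edible_volunteers",
    "food_production",
    "COMMERCIAL_LAND_USES",
    "COMMUNITY_LAND_USES",
    "DEFAULT_JOBS_RATE",
    "DEFAULT_VOLUNTEERS_RATE",
]

#: Urban-agriculture land uses with commercial purpose (create jobs).
COMMERCIAL_LAND_USES = ("Commercial garden", "Hydroponic rooftop")
#: Urban-agriculture land uses with community purpose (involve volunteers).
COMMUNITY_LAND_USES = ("Community garden", "Rooftop garden")

#: Jobs per m2 of growing surface (lo, hi).
DEFAULT_JOBS_RATE = (0.000163, 0.022)
#: Volunteers per m2 of growing surface (lo, hi).
DEFAULT_VOLUNTEERS_RATE = (0.00163, 0.22)

N_ITER = 1000


def mc_interval(
    areas: Sequence[float],
    lo,
    hi,
    mode: str = "global",
    n_iter: int = N_ITER,
    interval: float = 0.95,
    rng: int | np.random.Generator | None = None,
    verbose: bool = False,
) -> IntervalEstimate | np.ndarray:
    """Monte-Carlo interval for a linear per-area indicator.

    Each iteration computes sum(area_i * k_i) with k drawn uniformly from
    [lo, hi] once per iteration (``mode="global"``, scalar bounds) or
    independently per element (``mode="per-element"``, scalar or
    per-element bounds).  Returns the ((1-interval)/2, 0.5,
    1-(1-interval)/2) empirical quantiles of the totals, or all totals
    when ``verbose``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < interval < 1:
        raise ValueError("interval must lie in (0, 1)")
    rng = make_rng(rng)
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        totals = np.zeros(n_iter)
    elif mode == "global":
        lo_s, hi_s = float(np.asarray(lo)), float(np.asarray(hi))
        k = rng.uniform(lo_s, hi_s, size=n_iter)
        totals = k * areas.sum()
    elif mode == "per-element":
        lo_a = np.broadcast_to(np.asarray(lo, dtype=float), areas.shape)
        hi_a = np.broadcast_to(np.asarray(hi, dtype=float), areas.shape)
        draws = rng.uniform(lo_a, hi_a, size=(n_iter, areas.size))
        totals = draws @ areas
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if verbose:
        return totals
    alpha = (1.0 - interval) / 2.0
    lo_q, med, hi_q = np.quantile(totals, [alpha, 0.5, 1.0 - alpha])
    return IntervalEstimate(float(lo_q), float(med), float(hi_q), interval)


def no2_seq(
    city: CityModel,
    table: AttributeTable,
    rng: int | np.random.Generator | None = None,
) -> float:
    """Total NO2 sequestered by urban green, sum(a_i * cap_i) / 1000.

    a_i is the vegetated area of element i (area * pGreen; edible_area
    for urban-agriculture solutions) and cap_i a capacity drawn uniformly
    from the land use's [no2_seq1, no2_seq2] range (ug s^-1 m^-2).
    """
    rng = make_rng(rng)
    if len(city) == 0:
        return 0.0
    land_uses = city.df["land_use"].tolist()
    pgreen = table.col("pGreen", land_uses).astype(float)
    edible = table.col("edible", land_uses).astype(bool)
    lo = table.col("no2_seq1", land_uses).astype(float)
    hi = table.col("no2_seq2", land_uses).astype(float)
    area = city.df["area"].to_numpy()
    eff_area = np.where(edible, city.df["edible_area"].to_numpy(),
                        area * pgreen)
    cap = rng.uniform(lo, hi)
    return float((eff_area * cap).sum() / 1000.0)


def _purpose_areas(
    city: CityModel,
    land_uses: Sequence[str],
    area_col: str,
) -> np.ndarray:
    mask = city.df["land_use"].isin(set(land_uses))
    return city.df.loc[mask, area_col].to_numpy(dtype=float)


def edible_jobs(
    city: CityModel,
    table: AttributeTable,
    jobs: tuple[float, float] = DEFAULT_JOBS_RATE,
    edible: Sequence[str] | None = None,
    area_col: str = "edible_area",
    interval: float = 0.95,
    rng: int | np.random.Generator | None = None,
    verbose: bool = False,
    n_iter: int = N_ITER,
) -> IntervalEstimate | np.ndarray:
    """Jobs created in commercial urban agriculture (Monte-Carlo interval).

    ``edible`` overrides the default commercial land uses.  With no
    commercial element the interval degenerates to zero.
    """
    table.check_covers(city.df["land_use"].tolist())
    cats = COMMERCIAL_LAND_USES if edible is None else edible
    areas = _purpose_areas(city, cats, area_col)
    return mc_interval(areas, jobs[0], jobs[1], mode="global",
                       n_iter=n_iter, interval=interval, rng=rng,
                       verbose=verbose)


def edible_volunteers(
    city: CityModel,
    table: AttributeTable,
    volunteers: tuple[float, float] = DEFAULT_VOLUNTEERS_RATE,
    edible: Sequence[str] | None = None,
    area_col: str = "edible_area",
    interval: float = 0.95,
    rng: int | np.random.Generator | None = None,
    verbose: bool = False,
    n_iter: int = N_ITER,
) -> IntervalEstimate | np.ndarray:
    """Volunteers involved in community urban agriculture (Monte-Carlo
    interval); mirrors :func:`edible_jobs` over community land uses."""
    table.check_covers(city.df["land_use"].tolist())
    cats = COMMUNITY_LAND_USES if edible is None else edible
    areas = _purpose_areas(city, cats, area_col)
    return mc_interval(areas, volunteers[0], volunteers[1], mode="global",
                       n_iter=n_iter, interval=interval, rng=rng,
                       verbose=verbose)


def food_production(
    city: CityModel,
    table: AttributeTable,
    edible_df: pd.DataFrame | None = None,
    area_col: str | None = "edible_area",
    interval: float = 0.95,
    rng: int | np.random.Generator | None = None,
    verbose: bool = False,
    n_iter: int = N_ITER,
) -> IntervalEstimate | np.ndarray:
    """Yearly food production (kg/yr) of urban-agriculture elements.

    Per iteration the yield of each element is drawn uniformly from its
    category's [food1, food2] range (kg/m2/yr) and multiplied by its
    growing surface (``area_col``; the full element area when None).
    ``edible_df`` may override the yield table with columns land_uses /
    land_use, food1, food2.
    """
    if edible_df is not None:
        ed = edible_df.rename(columns={"land_uses": "land_use"})
        ed = ed.set_index("land_use") if ed.index.name != "land_use" else ed
        edible_cats = list(ed.index)
        food1 = ed["food1"]
        food2 = ed["food2"]
    else:
        edible_cats = table.flagged("edible")
        food1 = table.df["food1"]
        food2 = table.df["food2"]
    mask = city.df["land_use"].isin(set(edible_cats))
    sub = city.df[mask]
    areas = (sub[area_col] if area_col else sub["area"]).to_numpy(dtype=float)
    lus = sub["land_use"].tolist()
    lo = food1.loc[lus].to_numpy(dtype=float) if len(lus) else np.array([])
    hi = food2.loc[lus].to_numpy(dtype=float) if len(lus) else np.array([])
    return mc_interval(areas, lo, hi, mode="per-element", n_iter=n_iter,
                       interval=interval, rng=rng, verbose=verbose)
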