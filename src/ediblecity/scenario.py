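"""Urban-agriculture scenario generation.

``set_scenario`` converts a configurable share of private gardens, ground
plots and rooftops into five urban-agriculture solution types:

========================  ===============  ==========
solution                  location         purpose
========================  ===============  ==========
Edible private garden     private gardens  private
Community garden          plots on ground  community
Commercial garden         plots on ground  commercial
Rooftop garden            rooftops         community
Hydroponic rooftop        rooftops         commercial
========================  ===============  ==========

Candidate elements are drawn from configurable source land uses, filtered
by a minimum available area, and selected uniformly at random — except
commercial conversions, which take the largest available locations
(commercial initiatives are assumed to secure the best spots).  Each
converted element receives an ``edible_area`` drawn uniformly from a
per-class fraction range of its available surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import CityModel, make_rng

__all__ = ["ScenarioParams", "set_scenario"]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _check_fraction(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def _check_range(name: str, rng_: Sequence[float]) -> None:
    lo, hi = rng_
    if not (0 <= lo <= hi <= 1):
        raise ValueError(f"{name} must be a [lo, hi] range within [0, 1]")


@dataclass
class ScenarioParams:
    """Knobs of the scenario generator (defaults are the package's
    standard configuration).

    ``pGardens``/``pVacant``/``pRooftop`` are the proportions of candidate
    elements of each location class to convert; ``edible_area_*`` the
    fraction ranges of the available surface dedicated to growing plants;
    ``min_area_*`` the eligibility thresholds in m²; ``*_from`` the source
    land uses; ``pCommercial`` the share of ground/rooftop conversions
    given a commercial purpose; ``area_field`` the attribute used as
    available surface.
    """

    pGardens: float = 1.0
    pVacant: float = 1.0
    pRooftop: float = 1.0
    edible_area_garden: tuple[float, float] = (0.02, 0.3)
    edible_area_vacant: tuple[float, float] = (0.52, 0.75)
    edible_area_rooftop: tuple[float, float] = (0.6, 0.62)
    min_area_garden: float = 10.0
    min_area_vacant: float = 100.0
    min_area_rooftop: float = 100.0
    private_gardens_from: tuple[str, ...] = ("Normal garden",)
    vacant_from: tuple[str, ...] = ("Vacant",)
    rooftop_from: tuple[str, ...] = ("Rooftop",)
    pCommercial: float = 0.0
    area_field: str = "flat_area"
    quiet: bool = False

    def __post_init__(self) -> None:
        for name in ("pGardens", "pVacant", "pRooftop", "pCommercial"):
            _check_fraction(name, getattr(self, name))
        for name in ("edible_area_garden", "edible_area_vacant",
                     "edible_area_rooftop"):
            _check_range(name, getattr(self, name))
        for name in ("min_area_garden", "min_area_vacant",
                     "min_area_rooftop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("private_gardens_from", "vacant_from", "rooftop_from"):
            v = getattr(self, name)
            if isinstance(v, str):
                setattr(self, name, (v,))
            else:
                setattr(self, name, tuple(v))


# (noun used in warnings, min-area parameter name, community target,
#  commercial target); private gardens have a single target.
_CLASSES = (
    ("gardens", "private gardens", "min_area_garden",
     "Edible private garden", None),
    ("vacant", "vacant plots", "min_area_vacant",
     "Community garden", "Commercial garden"),
    ("rooftop", "rooftops", "min_area_rooftop",
     "Rooftop garden", "Hydroponic rooftop"),
)


def set_scenario(
    city: CityModel,
    params: ScenarioParams | None = None,
    rng: int | np.random.Generator | None = None,
) -> tuple[CityModel, list[str]]:
    """Build a new scenario city by converting elements to urban agriculture.

    Returns the converted :class:`CityModel` (same element count, ids and
    total area as the input; untouched elements identical) and the list of
    warning messages about classes where fewer eligible elements existed
    than the requested proportion implied.
    """
    params = params if params is not None else ScenarioParams()
    rng = make_rng(rng)
    df = city.df.copy()
    warnings_: list[str] = []

    if params.area_field not in df.columns:
        raise ValueError(f"area_field {params.area_field!r} not in city")
    area_vals = df[params.area_field].astype(float)

    # One independent substream per location class so that changing the
    # number of draws in one class never perturbs another's selection.
    streams = rng.spawn(3)

    for (key, noun, min_name, community_lu, commercial_lu), g in zip(
        _CLASSES, streams
    ):
        p = getattr(params, f"p{'Gardens' if key == 'gardens' else key.capitalize()}")
        sources = {
            "gardens": params.private_gardens_from,
            "vacant": params.vacant_from,
            "rooftop": params.rooftop_from,
        }[key]
        lo, hi = {
            "gardens": params.edible_area_garden,
            "vacant": params.edible_area_vacant,
            "rooftop": params.edible_area_rooftop,
        }[key]
        min_area = getattr(params, min_name)

        candidates = df.index[df["land_use"].isin(sources)]
        if len(candidates) == 0:
            if p > 0 and not params.quiet:
                warnings_.append(
                    f"No elements with land_use in {sorted(sources)} found "
                    f"for {noun}"
                )
            continue
        n_target = _round_half_away(p * len(candidates))
        if n_target == 0:
            continue
        eligible = candidates[area_vals.loc[candidates] >= min_area]
        n = n_target
        if len(eligible) < n_target:
            n = len(eligible)
            msg = (
                f"Only {len(eligible)} {noun} out of {n_target} assumed "
                f"satisfy the '{min_name}'"
            )
            if not params.quiet:
                warnings_.append(msg)
        if n == 0:
            continue

        if commercial_lu is None:
            order = g.permutation(len(eligible))
            chosen = eligible[order[:n]]
            assign = {eid: community_lu for eid in chosen}
        else:
            n_com = _round_half_away(params.pCommercial * n)
            # commercial purpose settles in the largest available locations
            by_size = eligible[np.argsort(-area_vals.loc[eligible].to_numpy(),
                                          kind="stable")]
            commercial = by_size[:n_com]
            remaining = by_size[n_com:]
            order = g.permutation(len(remaining))
            community = remaining[order[: n - n_com]]
            assign = {eid: commercial_lu for eid in commercial}
            assign.update({eid: community_lu for eid in community})

        # draw edible-area fractions in stable (layer) order for determinism
        chosen_ids = [eid for eid in df.index if eid in assign]
        u = g.uniform(lo, hi, size=len(chosen_ids))
        for frac, eid in zip(u, chosen_ids):
            df.at[eid, "land_use"] = assign[eid]
            df.at[eid, "edible_area"] = frac * area_vals.loc[eid]

    return CityModel(df, city.crs), warnings_
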