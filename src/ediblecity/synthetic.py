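"""Seedable synthetic fixtures: city, neighbourhoods and SVF raster.

The generator lays out a rectangular grid of square blocks separated by
streets and assigns each block a land use by configured fractions:
residential buildings ("Rooftop", with 1..n floors), vacant plots,
private gardens ("Normal garden"), public parks (Grass or Trees) and
paved plazas for the remainder.  Exactly one non-built block becomes a
pre-existing Community garden with a nonzero edible area, so the base
scenario already contains some urban agriculture.  The companion SVF
raster is a monotone kernel-density transform of built volume (1.0 over
open land, lower where tall buildings cluster) — plausible [0, 1]
structure for testing, not a photometric sky-view computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import box

from .core import CityModel, NeighbourhoodLayer, SvfGrid

__all__ = [
    "SyntheticConfig",
    "generate_city",
    "generate_neighbourhoods",
    "generate_svf",
]


@dataclass
class SyntheticConfig:
    """Layout and composition of the synthetic city."""

    blocks_x: int = 10
    blocks_y: int = 10
    block_size: float = 50.0
    street_width: float = 10.0
    building_fraction: float = 0.45
    vacant_fraction: float = 0.15
    garden_fraction: float = 0.15
    park_fraction: float = 0.15
    floors_range: tuple[int, int] = (1, 6)
    inhabitants_per_residence: int = 40
    seed: int = 0
    crs: str = "EPSG:25831"
    x_origin: float = 480000.0
    y_origin: float = 4640000.0

    def __post_init__(self) -> None:
        if self.blocks_x < 1 or self.blocks_y < 1:
            raise ValueError("grid dimensions must be >= 1")
        fracs = (self.building_fraction, self.vacant_fraction,
                 self.garden_fraction, self.park_fraction)
        if any(f < 0 for f in fracs):
            raise ValueError("fractions must be non-negative")
        if sum(fracs) > 1 + 1e-9:
            raise ValueError("fractions must sum to <= 1")
        if self.floors_range[0] < 0 or self.floors_range[0] > self.floors_range[1]:
            raise ValueError("invalid floors_range")


def generate_city(config: SyntheticConfig | None = None) -> CityModel:
    """Generate a block-grid city passing all city-model invariants.

    Deterministic for a fixed config (including its seed).
    """
    cfg = config if config is not None else SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    pitch = cfg.block_size + cfg.street_width
    x0, y0 = cfg.x_origin, cfg.y_origin

    rows: list[dict] = []

    def add(geom, land_use, verbose, floors=0, edible_area=0.0):
        area = geom.area
        rows.append(
            dict(land_use=land_use, land_use_verbose=verbose,
                 floors=int(floors), area=area, flat_area=area,
                 edible_area=float(edible_area), geometry=geom)
        )

    # street corridors between and around blocks
    width_total = cfg.blocks_x * pitch + cfg.street_width
    height_total = cfg.blocks_y * pitch + cfg.street_width
    for i in range(cfg.blocks_x + 1):
        x = x0 + i * pitch
        add(box(x, y0, x + cfg.street_width, y0 + height_total),
            "Streets", "Street")
    for j in range(cfg.blocks_y + 1):
        y = y0 + j * pitch
        # horizontal segments between the vertical corridors, one per gap
        for i in range(cfg.blocks_x):
            x = x0 + cfg.street_width + i * pitch
            add(box(x, y, x + cfg.block_size, y + cfg.street_width),
                "Streets", "Street")

    kinds = ("Rooftop", "Vacant", "Normal garden", "Park", "Streets")
    probs = np.array(
        [cfg.building_fraction, cfg.vacant_fraction, cfg.garden_fraction,
         cfg.park_fraction, 0.0]
    )
    probs[-1] = max(0.0, 1.0 - probs.sum())
    probs = probs / probs.sum()

    block_records = []
    for j in range(cfg.blocks_y):
        for i in range(cfg.blocks_x):
            x = x0 + cfg.street_width + i * pitch
            y = y0 + cfg.street_width + j * pitch
            geom = box(x, y, x + cfg.block_size, y + cfg.block_size)
            kind = rng.choice(len(kinds), p=probs)
            block_records.append((geom, kinds[kind]))

    # exactly one pre-existing community garden on a non-built block
    open_idx = [k for k, (_, kind) in enumerate(block_records)
                if kind != "Rooftop"]
    cg_idx = int(rng.choice(open_idx)) if open_idx else None

    for k, (geom, kind) in enumerate(block_records):
        if k == cg_idx:
            add(geom, "Community garden", "Community garden",
                edible_area=0.4 * geom.area)
        elif kind == "Rooftop":
            floors = int(rng.integers(cfg.floors_range[0],
                                      cfg.floors_range[1] + 1))
            add(geom, "Rooftop", "Residence", floors=floors)
        elif kind == "Vacant":
            add(geom, "Vacant", "Vacant")
        elif kind == "Normal garden":
            add(geom, "Normal garden", "Private garden")
        elif kind == "Park":
            lu = "Grass" if rng.uniform() < 0.5 else "Trees"
            add(geom, lu, "Park")
        else:
            add(geom, "Streets", "Plaza")

    df = pd.DataFrame(rows)
    df.index.name = "id"
    return CityModel(df, cfg.crs)


def generate_neighbourhoods(
    city: CityModel,
    n: int = 2,
    inhabitants: list[int] | None = None,
) -> NeighbourhoodLayer:
    """Partition the city extent into ``n`` vertical slabs with the given
    populations."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if inhabitants is None:
        n_res = int((city.df["land_use_verbose"] == "Residence").sum())
        base = max(1, n_res) * 40
        inhabitants = [base // n] * n
    if len(inhabitants) != n:
        raise ValueError("inhabitants must have length n")
    minx, miny, maxx, maxy = shapely.total_bounds(city.geometry)
    edges = np.linspace(minx, maxx, n + 1)
    rows = [
        dict(name=f"district-{k}", inhabitants=int(inhabitants[k]),
             geometry=box(edges[k], miny, edges[k + 1], maxy))
        for k in range(n)
    ]
    return NeighbourhoodLayer(pd.DataFrame(rows), city.crs)


def generate_svf(city: CityModel, cell_size: float = 10.0) -> SvfGrid:
    """Synthetic sky-view-factor raster aligned to the city bounds.

    SVF is 1 over open land and decreases with the floor-weighted density
    of buildings within a smoothing kernel, so the densest built cluster
    holds the grid's minimum.  Deterministic given the city.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    minx, miny, maxx, maxy = shapely.total_bounds(city.geometry)
    ncol = max(1, int(np.ceil((maxx - minx) / cell_size)))
    nrow = max(1, int(np.ceil((maxy - miny) / cell_size)))
    y_top = miny + nrow * cell_size
    grid = SvfGrid(np.ones((nrow, ncol)), minx, y_top, cell_size, city.crs)

    built = city.df["floors"].to_numpy() > 0
    if not built.any():
        return grid
    X, Y = grid.cell_centers()
    points = shapely.points(X, Y)
    tree = shapely.STRtree(city.geometry[built])
    pi, gi = tree.query(points, predicate="within")
    floors = city.df["floors"].to_numpy()[built]
    density = np.zeros(nrow * ncol)
    density[pi] = floors[gi]
    density = density.reshape(nrow, ncol)
    sigma_cells = max(1.0, 30.0 / cell_size)  # ~30 m smoothing radius
    density = ndimage.gaussian_filter(density, sigma=sigma_cells)
    peak = density.max()
    if peak > 0:
        grid.values = 1.0 - 0.85 * density / peak
    return grid
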