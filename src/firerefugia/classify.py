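"""Assign leks to fire-context categories from perimeters and islands.

Each lek falls into exactly one of four categories relative to the mapped
fire history, applied in precedence order:

1. ``UNBURNED_ISLAND`` — inside an unburned island, or within 50 m of an
   island edge or of a fire-perimeter edge (on either side);
2. ``FIRE_PERIMETER`` — inside a burned perimeter interior;
3. ``SMALL_BUFFER`` — 50 m to 1.5 km outside the nearest perimeter;
4. ``LARGE_BUFFER`` — 1.5 km to 6.4 km outside the nearest perimeter;
5. ``OUTSIDE`` — farther than 6.4 km; such leks are excluded downstream.

Distances are planar Euclidean distances from the lek point to polygon
edges, which keeps the 50 m rule resolution-independent.  Boundary
conventions (the sources leave them open): "<50 m" is strict; the small
buffer is closed at 50 m and open at 1.5 km; the large buffer is closed at
both 1.5 and 6.4 km.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from shapely import Point, union_all
from shapely.geometry.base import BaseGeometry

from .grid import RasterGrid
from .synthetic import FireHistoryLayers, mask_to_polygons

__all__ = ["FireCategory", "LekFireAssignment", "classify_lek", "classify_leks"]

#: analysis distance thresholds in meters
ISLAND_NEAR_M = 50.0
SMALL_BUFFER_MAX_M = 1_500.0
LARGE_BUFFER_MAX_M = 6_400.0


class FireCategory(str, Enum):
    UNBURNED_ISLAND = "unburned_island"
    FIRE_PERIMETER = "fire_perimeter"
    SMALL_BUFFER = "small_buffer"
    LARGE_BUFFER = "large_buffer"
    OUTSIDE = "outside"


@dataclass
class LekFireAssignment:
    """One lek's fire-context category and the fire year that drives it.

    ``dist_to_perimeter_m`` is signed: negative means the lek lies inside a
    perimeter.  ``dist_to_island_m`` is None when no islands are mapped.
    """

    lek_id: str
    category: FireCategory
    burn_year: int | None
    dist_to_perimeter_m: float
    dist_to_island_m: float | None


def _nearest_fire(pt: Point, perimeters: list[tuple[BaseGeometry, int]]) -> tuple[float, int | None]:
    """Signed distance to the nearest perimeter and its fire year.

    A containing perimeter has negative distance (to its boundary).  All
    containing perimeters rank equally near (distance 0 for the choice);
    ties are broken by the earliest fire year, as the earliest disturbance
    drives the habitat state.
    """
    best_rank, best_d, best_year = np.inf, np.inf, None
    for poly, year in perimeters:
        if year is None:
            raise ValueError("perimeter missing fire year")
        d = poly.boundary.distance(pt)
        if poly.contains(pt):
            d = -d
        rank = max(d, 0.0)
        if rank < best_rank - 1e-9 or (
            abs(rank - best_rank) <= 1e-9 and (best_year is None or year < best_year)
        ):
            best_rank, best_d, best_year = rank, d, year
    return float(best_d), best_year


def classify_lek(
    lek_id: str,
    lek_xy: tuple[float, float],
    perimeters: list[tuple[BaseGeometry, int]],
    island_geom: BaseGeometry | None,
    *,
    extent: tuple[float, float, float, float] | None = None,
    island_near_m: float = ISLAND_NEAR_M,
    small_buffer_max_m: float = SMALL_BUFFER_MAX_M,
    large_buffer_max_m: float = LARGE_BUFFER_MAX_M,
) -> LekFireAssignment:
    """Classify one lek point against the fire history.

    Parameters
    ----------
    perimeters
        (polygon, fire_year) pairs in the same planar CRS as the lek.
    island_geom
        Union geometry of unburned-island cells (see
        :func:`islands_as_geometry`), or None when no islands exist.
    extent
        Optional (xmin, ymin, xmax, ymax) check; a lek outside it is an
        error rather than a silent OUTSIDE.
    """
    x, y = lek_xy
    if extent is not None:
        xmin, ymin, xmax, ymax = extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(f"lek {lek_id} at ({x}, {y}) lies outside the raster extent")
    pt = Point(x, y)

    if not perimeters:
        return LekFireAssignment(lek_id, FireCategory.OUTSIDE, None, np.inf, None)

    d_perim, fire_year = _nearest_fire(pt, perimeters)
    d_island: float | None = None
    if island_geom is not None and not island_geom.is_empty:
        d_island = float(island_geom.distance(pt))  # 0 when inside

    near_island = d_island is not None and d_island < island_near_m
    near_perimeter_edge = abs(d_perim) < island_near_m
    if near_island or near_perimeter_edge:
        category = FireCategory.UNBURNED_ISLAND
    elif d_perim < 0:
        category = FireCategory.FIRE_PERIMETER
    elif d_perim < small_buffer_max_m:
        category = FireCategory.SMALL_BUFFER
    elif d_perim <= large_buffer_max_m:
        category = FireCategory.LARGE_BUFFER
    else:
        category = FireCategory.OUTSIDE

    burn_year = fire_year if category is not FireCategory.OUTSIDE else None
    return LekFireAssignment(lek_id, category, burn_year, d_perim, d_island)


def islands_as_geometry(island_mask: RasterGrid) -> BaseGeometry:
    """Polygonize the unburned-island mask for vector distance queries."""
    return mask_to_polygons(island_mask.data.astype(bool), island_mask)


def classify_leks(
    leks: "pd.DataFrame",
    fire_history: FireHistoryLayers,
    *,
    island_near_m: float = ISLAND_NEAR_M,
    small_buffer_max_m: float = SMALL_BUFFER_MAX_M,
    large_buffer_max_m: float = LARGE_BUFFER_MAX_M,
) -> "pd.DataFrame":
    """Classify every lek in a (lek_id, x, y) table.

    Returns a DataFrame with columns lek_id, category, burn_year,
    dist_to_perimeter_m, dist_to_island_m.
    """
    import pandas as pd

    island_geom = islands_as_geometry(fire_history.island_mask)
    extent = fire_history.burn_year.extent
    out = []
    for row in leks.itertuples(index=False):
        a = classify_lek(
            str(row.lek_id), (float(row.x), float(row.y)), fire_history.perimeters, island_geom,
            extent=extent,
            island_near_m=island_near_m,
            small_buffer_max_m=small_buffer_max_m,
            large_buffer_max_m=large_buffer_max_m,
        )
        out.append(
            {
                "lek_id": a.lek_id,
                "category": a.category.value,
                "burn_year": a.burn_year if a.burn_year is not None else pd.NA,
                "dist_to_perimeter_m": a.dist_to_perimeter_m,
                "dist_to_island_m": a.dist_to_island_m if a.dist_to_island_m is not None else pd.NA,
            }
        )
    return pd.DataFrame(out)
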