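"""Simulated postfire habitat surfaces and multiscale lek covariates.

Burning is simulated from the fire record rather than observed: for a lek
that burned in year T, every cell whose most recent fire falls in
[T-17, T] counts as burned (sagebrush needs 35-120 years to recover, so a
17-year-old burn is still unsuitable).  On the burned surface,

- vegetation height of burned cells and of unsuitable types (forest,
  juniper) is 0 m; unburned sagebrush keeps its height-class midpoint
  (0.25 m for the 0-0.5 m class, ..., 3.25 m for '>3 m');
- cheatgrass suitability follows an elevation-thresholded rule: burned
  cells below 2,000 m are unsuitable (>8% cover assumed after invasion),
  burned cells at or above 2,000 m are suitable, and unburned cells are
  unsuitable only where observed cover exceeds 8%.

Covariates are extracted for discs of 0.8, 6.4 and 18 km radius around the
lek: mean height over unburned sagebrush cells, fraction of disc cells
with unsuitable cheatgrass, and mean elevation over all disc cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid, disc_mask
from .synthetic import BURN_NODATA, VEG_FOREST, VEG_JUNIPER, VEG_SAGEBRUSH

__all__ = [
    "PostfireSurfaces",
    "HabitatCovariates",
    "SCALE_RADII_M",
    "delineate_burned",
    "postfire_height",
    "postfire_cheatgrass",
    "resample_nearest",
    "build_surfaces",
    "extract_covariates",
]

#: analysis radii in meters (fine / intermediate / landscape scale)
SCALE_RADII_M = (800.0, 6_400.0, 18_000.0)

LOOKBACK_YEARS = 17
CHEAT_COVER_THRESHOLD = 8.0  # percent
CHEAT_ELEVATION_M = 2_000.0
HEIGHT_CLASS_WIDTH_M = 0.5
TOP_CLASS_MIDPOINT_M = 3.25  # the open-ended '>3 m' class


@dataclass
class PostfireSurfaces:
    """Co-registered 30 m surfaces for one lek's fire year."""

    burned_mask: RasterGrid  # bool
    height_m: RasterGrid
    cheat_unsuitable: RasterGrid  # bool
    elevation_m: RasterGrid


@dataclass
class HabitatCovariates:
    """The nine per-lek covariates: three variables at three radii."""

    lek_id: str
    fire_year: int
    veg_height: tuple[float, float, float]
    cheat_frac: tuple[float, float, float]
    elevation: tuple[float, float, float]


def delineate_burned(
    fire_year: int, burn_year: RasterGrid, lookback_years: int = LOOKBACK_YEARS
) -> RasterGrid:
    """Cells whose most recent burn year falls in [fire_year-17, fire_year]."""
    b = burn_year.data
    mask = (b != burn_year.nodata) & (b >= fire_year - lookback_years) & (b <= fire_year)
    return burn_year.copy_with(mask)


def height_class_midpoint(code: np.ndarray) -> np.ndarray:
    """Midpoint height in meters of 0.5 m class codes 1..7 ('>3 m' -> 3.25)."""
    code = np.asarray(code)
    mid = (code - 0.5) * HEIGHT_CLASS_WIDTH_M
    return np.where(code >= 7, TOP_CLASS_MIDPOINT_M, mid)


def postfire_height(
    height_class: RasterGrid, veg_type: RasterGrid, burned_mask: RasterGrid
) -> RasterGrid:
    """Postfire vegetation height: sagebrush midpoints, 0 elsewhere.

    Burned cells and unsuitable vegetation types (forest, juniper) are set
    to 0 m; only unburned sagebrush retains its class-midpoint height.
    """
    for other in (veg_type, burned_mask):
        if not height_class.same_grid_as(other):
            raise ValueError("height, vegetation and burn rasters must share one grid")
    h = height_class_midpoint(height_class.data).astype(float)
    unsuitable = np.isin(veg_type.data, (VEG_FOREST, VEG_JUNIPER))
    not_sage = veg_type.data != VEG_SAGEBRUSH
    h[burned_mask.data.astype(bool) | unsuitable | not_sage] = 0.0
    return height_class.copy_with(h)


def resample_nearest(coarse: RasterGrid, template: RasterGrid) -> RasterGrid:
    """Nearest-neighbor resampling of a coarse raster onto a template grid."""
    X, Y = template.cell_centers()
    x0, y0 = coarse.origin
    cols = np.clip(((X - x0) / coarse.cell_size).astype(int), 0, coarse.data.shape[1] - 1)
    rows = np.clip(((y0 - Y) / coarse.cell_size).astype(int), 0, coarse.data.shape[0] - 1)
    return template.copy_with(coarse.data[rows, cols])


def postfire_cheatgrass(
    cheat_cover: RasterGrid,
    burned_mask: RasterGrid,
    elevation: RasterGrid,
    *,
    cover_threshold_pct: float = CHEAT_COVER_THRESHOLD,
    elevation_threshold_m: float = CHEAT_ELEVATION_M,
) -> RasterGrid:
    """Boolean unsuitable-cheatgrass surface after the burn rules.

    ``cheat_cover`` may be on a coarser grid (250 m source data); it is
    nearest-neighbor resampled onto the analysis grid first, which
    preserves the observed cover values.  Cells at exactly 2,000 m follow
    the at-or-above branch (suitable when burned).
    """
    if not burned_mask.same_grid_as(elevation):
        raise ValueError("burn and elevation rasters must share one grid")
    if not cheat_cover.same_grid_as(burned_mask):
        cheat_cover = resample_nearest(cheat_cover, burned_mask)
    cover = cheat_cover.data
    if np.any(cover < 0) or np.any(cover > 100):
        raise ValueError("cheatgrass cover must lie in [0, 100] percent")
    burned = burned_mask.data.astype(bool)
    low = elevation.data < elevation_threshold_m
    unsuitable = np.where(burned, low, cover > cover_threshold_pct)
    return burned_mask.copy_with(unsuitable)


def build_surfaces(
    fire_year: int,
    burn_year: RasterGrid,
    height_class: RasterGrid,
    veg_type: RasterGrid,
    cheat_cover: RasterGrid,
    elevation: RasterGrid,
    *,
    lookback_years: int = LOOKBACK_YEARS,
    cover_threshold_pct: float = CHEAT_COVER_THRESHOLD,
    elevation_threshold_m: float = CHEAT_ELEVATION_M,
) -> PostfireSurfaces:
    """Assemble all postfire surfaces for one lek fire year."""
    burned = delineate_burned(fire_year, burn_year, lookback_years)
    return PostfireSurfaces(
        burned_mask=burned,
        height_m=postfire_height(height_class, veg_type, burned),
        cheat_unsuitable=postfire_cheatgrass(
            cheat_cover, burned, elevation,
            cover_threshold_pct=cover_threshold_pct,
            elevation_threshold_m=elevation_threshold_m,
        ),
        elevation_m=elevation,
    )


def extract_covariates(
    lek_id: str,
    lek_xy: tuple[float, float],
    fire_year: int,
    surfaces: PostfireSurfaces,
    radii_m: tuple[float, ...] = SCALE_RADII_M,
) -> HabitatCovariates:
    """Disc means/fractions of the postfire surfaces around one lek.

    Per radius: mean postfire height over *unburned sagebrush* cells
    (cells with height > 0; 0 when the disc holds none), fraction of disc
    cells flagged cheatgrass-unsuitable, and mean elevation over all disc
    cells.  Disc membership is cell-center-in-circle; a disc extending
    beyond the raster is an error, so synthetic extents must pad the
    largest radius.
    """
    grid = surfaces.elevation_m
    veg_height, cheat_frac, elev_mean = [], [], []
    for r in radii_m:
        disc = disc_mask(grid, lek_xy, r)
        n = int(disc.sum())
        if n == 0:
            raise ValueError(f"disc of radius {r} m contains no cell centers")
        h = surfaces.height_m.data[disc]
        standing = h > 0
        veg_height.append(float(h[standing].mean()) if standing.any() else 0.0)
        cheat_frac.append(float(surfaces.cheat_unsuitable.data[disc].sum()) / n)
        elev_mean.append(float(surfaces.elevation_m.data[disc].mean()))
    return HabitatCovariates(
        lek_id=lek_id,
        fire_year=fire_year,
        veg_height=tuple(veg_height),
        cheat_frac=tuple(cheat_frac),
        elevation=tuple(elev_mean),
    )
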