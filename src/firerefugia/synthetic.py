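"""Synthetic fire-mosaic landscapes and lek count series with known truth.

Real inputs for this analysis are fire perimeters with an unburned-island
mask, 30 m vegetation type / height-class rasters, a 250 m invasive-grass
(cheatgrass) cover raster, an elevation model, and yearly peak male counts
at leks.  This module fabricates all of them on a planar grid so that every
downstream stage — fire-context classification, before/after Poisson trend
fitting, habitat extraction, and multimodel inference — can be exercised
end-to-end against planted ground truth.

Fires are blob-shaped regions produced by thresholding spatially smoothed
noise around random ignition points; unburned islands are carved out of
each fire interior with a second, higher threshold of the same kind of
field, which yields contiguous patches with a controllable island
fraction.  Count series follow a log-linear Poisson model with separate
pre- and postfire slopes:

    E(ln Y) = b0 + b1*X1 + b2*X2 + b3*X1*X2

with X1 the (centered) survey year and X2 the after-fire indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely import box as shp_box
from shapely import union_all
from shapely.geometry.base import BaseGeometry

from .grid import RasterGrid

__all__ = [
    "LandscapeConfig",
    "TrueLekParams",
    "FireHistoryLayers",
    "SyntheticLandscape",
    "VEG_SAGEBRUSH",
    "VEG_GRASS",
    "VEG_FOREST",
    "VEG_JUNIPER",
    "BURN_NODATA",
    "generate_landscape",
    "mask_to_polygons",
    "simulate_lek_counts",
    "place_leks",
]

# vegetation type codes
VEG_SAGEBRUSH = 1
VEG_GRASS = 2
VEG_FOREST = 3
VEG_JUNIPER = 4

#: nodata code of the burn-year raster (cell never burned)
BURN_NODATA = -9999


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic study landscape.

    Defaults mirror the study system: a sagebrush steppe between 1,120 and
    2,750 m elevation with a 1984-2014 fire record, 30 m vegetation grids,
    a 250 m cheatgrass-cover grid, and per-fire unburned-island fractions
    spanning roughly 2-78% of the perimeter area with a mean near 10%.
    """

    extent_m: tuple[float, float] = (30_000.0, 30_000.0)
    cell_size_m: float = 30.0
    cheat_cell_size_m: float = 250.0
    n_fires: int = 5
    unburned_fraction_range: tuple[float, float] = (0.02, 0.78)
    #: Beta(a, b) shape of the island-fraction draw inside the range above;
    #: (1.2, 10) gives mean ~0.10 and median ~0.08 of perimeter area.
    island_fraction_beta: tuple[float, float] = (1.2, 10.0)
    fire_area_km2_range: tuple[float, float] = (4.05, 60.0)
    elevation_range_m: tuple[float, float] = (1120.0, 2750.0)
    years: tuple[int, int] = (1984, 2014)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.extent_m
        if w <= 0 or h <= 0:
            raise ValueError("extent must have positive area")
        if self.cell_size_m <= 0 or self.cheat_cell_size_m <= 0:
            raise ValueError("cell sizes must be positive")
        if self.n_fires < 0:
            raise ValueError("n_fires must be >= 0")
        lo, hi = self.unburned_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("unburned_fraction_range must be ordered within [0, 1]")
        if self.years[1] - self.years[0] < 1:
            raise ValueError("year span must cover at least 2 years")
        for ext in self.extent_m:
            if abs(ext / self.cell_size_m - round(ext / self.cell_size_m)) > 1e-9:
                raise ValueError("extent must divide into whole cells")

    @property
    def shape(self) -> tuple[int, int]:
        w, h = self.extent_m
        return int(round(h / self.cell_size_m)), int(round(w / self.cell_size_m))


@dataclass
class TrueLekParams:
    """Ground-truth generating parameters of one lek's count series.

    ``beta0`` is the log mean count at the fire year, ``beta1`` the prefire
    log-linear trend per year, ``beta2`` an immediate postfire level shift,
    and ``beta3`` the postfire change in trend (so the postfire slope is
    ``beta1 + beta3``).
    """

    lek_id: str
    x: float
    y: float
    beta0: float
    beta1: float
    beta3: float
    fire_year: int | None
    survey_years: tuple[int, ...]
    beta2: float = 0.0

    def __post_init__(self) -> None:
        if len(self.survey_years) == 0:
            raise ValueError("survey_years must be nonempty")
        self.survey_years = tuple(sorted(self.survey_years))


@dataclass
class FireHistoryLayers:
    """Burn-year raster, unburned-island mask, and perimeter polygons."""

    burn_year: RasterGrid  # int raster; BURN_NODATA outside all fires
    island_mask: RasterGrid  # bool raster; True only inside perimeters
    perimeters: list[tuple[BaseGeometry, int]]  # (polygon, fire year)


@dataclass
class SyntheticLandscape:
    config: LandscapeConfig
    fire_history: FireHistoryLayers
    veg_type: RasterGrid
    height_class: RasterGrid  # codes 1..7 for 0.5 m bins, 7 = '>3 m'
    elevation: RasterGrid
    cheatgrass: RasterGrid  # percent cover 0-100 on the coarse grid


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise (a cheap random field).

    For large correlation lengths the field is generated on a decimated
    grid and spline-upsampled, which is indistinguishable for our use and
    orders of magnitude faster than filtering at full resolution.
    """
    factor = max(int(sigma // 4), 1)
    if factor > 1:
        coarse_shape = (max(shape[0] // factor + 2, 4), max(shape[1] // factor + 2, 4))
        f = ndimage.gaussian_filter(
            rng.standard_normal(coarse_shape), sigma=sigma / factor, mode="reflect"
        )
        f = ndimage.zoom(f, factor, order=1)[: shape[0], : shape[1]]
        if f.shape != shape:  # pad the odd remainder by edge replication
            f = np.pad(f, ((0, shape[0] - f.shape[0]), (0, shape[1] - f.shape[1])), mode="edge")
    else:
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _blob_mask(
    rng: np.random.Generator,
    shape: tuple[int, int],
    center_rc: tuple[float, float],
    n_cells: int,
    sigma: float,
    wiggle: float = 0.35,
) -> np.ndarray:
    """Blob of ~n_cells around center: smoothed noise minus a radial ramp,
    thresholded at the n_cells-th highest score.

    Work is confined to a window of ~6 blob radii around the center, which
    keeps per-fire cost independent of the landscape size.
    """
    nrows, ncols = shape
    radius = math.sqrt(n_cells / math.pi)
    half = int(min(max(3 * radius, 8), max(nrows, ncols)))
    r0 = max(int(center_rc[0]) - half, 0)
    r1 = min(int(center_rc[0]) + half + 1, nrows)
    c0 = max(int(center_rc[1]) - half, 0)
    c1 = min(int(center_rc[1]) + half + 1, ncols)
    wshape = (r1 - r0, c1 - c0)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rr - center_rc[0], cc - center_rc[1])
    score = wiggle * _smooth_field(rng, wshape, sigma) - dist / radius
    n_sel = min(n_cells, score.size)
    thresh = np.partition(score.ravel(), -n_sel)[-n_sel]
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = score >= thresh
    return mask


def mask_to_polygons(mask: np.ndarray, grid: RasterGrid) -> BaseGeometry:
    """Union of the world-coordinate squares of all True cells.

    Returns an empty geometry for an all-False mask.  Used both to trace
    synthetic fire perimeters and to polygonize island-mask cells for
    vector distance queries.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return union_all([])
    x0, y0 = grid.origin
    cs = grid.cell_size
    xmin = x0 + cols * cs
    xmax = xmin + cs
    ymax = y0 - rows * cs
    ymin = ymax - cs
    merged = union_all(shp_box(xmin, ymin, xmax, ymax))
    # drop collinear staircase vertices; keeps geometry identical
    return merged.simplify(0.0)


def generate_landscape(config: LandscapeConfig) -> SyntheticLandscape:
    """Generate all raster layers and fire history for one landscape.

    The same seed always yields bit-identical rasters: a single
    ``numpy.random.default_rng(config.rng_seed)`` stream drives every
    stochastic choice in a fixed order.
    """
    rng = np.random.default_rng(config.rng_seed)
    shape = config.shape
    nrows, ncols = shape
    cs = config.cell_size_m
    origin = (0.0, config.extent_m[1])

    # elevation: large-scale smooth field + a gentle gradient, rescaled
    # exactly onto the configured range
    sigma_elev = max(nrows, ncols) / 6
    grad = np.linspace(0, 1, ncols)[None, :] + np.linspace(0, 0.5, nrows)[:, None]
    elev = _smooth_field(rng, shape, sigma_elev) + 1.5 * grad
    lo, hi = config.elevation_range_m
    span = elev.max() - elev.min()
    elev = lo + (elev - elev.min()) / (span if span > 0 else 1.0) * (hi - lo)
    elevation = RasterGrid(elev, cs, origin)

    # vegetation type: sagebrush matrix with smooth-field patches of grass,
    # forest and juniper (~80/10/5/5 by area)
    veg_field = _smooth_field(rng, shape, sigma=max(nrows, ncols) / 20)
    veg = np.full(shape, VEG_SAGEBRUSH, dtype=np.int16)
    q80, q90, q95 = np.quantile(veg_field, [0.80, 0.90, 0.95])
    veg[veg_field > q80] = VEG_GRASS
    veg[veg_field > q90] = VEG_FOREST
    veg[veg_field > q95] = VEG_JUNIPER
    veg_type = RasterGrid(veg, cs, origin)

    # vegetation height class: codes 1..7 for the 0.5 m bins (7 = '>3 m'),
    # drawn from a smooth field so stands are spatially coherent
    h_field = _smooth_field(rng, shape, sigma=max(nrows, ncols) / 25)
    edges = np.quantile(h_field, [0.15, 0.45, 0.70, 0.85, 0.93, 0.98])
    hclass = (np.digitize(h_field, edges) + 1).astype(np.int16)
    height_class = RasterGrid(hclass, cs, origin)

    # fires: blob perimeters with most-recent-burn-year mosaic semantics
    burn = np.full(shape, BURN_NODATA, dtype=np.int32)
    islands = np.zeros(shape, dtype=bool)
    perimeters: list[tuple[BaseGeometry, int]] = []
    y0, y1 = config.years
    a_lo, a_hi = config.fire_area_km2_range
    cell_km2 = (cs / 1000.0) ** 2
    max_cells = int(0.4 * burn.size)
    f_lo, f_hi = config.unburned_fraction_range
    beta_a, beta_b = config.island_fraction_beta
    for _ in range(config.n_fires):
        center = (rng.uniform(0, nrows), rng.uniform(0, ncols))
        area_km2 = math.exp(rng.uniform(math.log(a_lo), math.log(a_hi)))
        n_cells = min(max(int(area_km2 / cell_km2), 16), max_cells)
        fire_year = int(rng.integers(y0, y1 + 1))
        fire_mask = _blob_mask(rng, shape, center, n_cells, sigma=max(8, math.sqrt(n_cells) / 3))

        # islands: highest-scoring patches of a finer smooth field inside
        # the perimeter; exact-count threshold pins the island fraction
        frac = f_lo + (f_hi - f_lo) * rng.beta(beta_a, beta_b)
        inside = np.nonzero(fire_mask)
        n_inside = inside[0].size
        k = int(round(frac * n_inside))
        fire_islands = np.zeros(shape, dtype=bool)
        if k > 0:
            # island field only needs the fire's bounding window
            r0, r1 = inside[0].min(), inside[0].max() + 1
            c0, c1 = inside[1].min(), inside[1].max() + 1
            isl_field = _smooth_field(
                rng, (r1 - r0, c1 - c0), sigma=max(3, math.sqrt(n_cells) / 6)
            )
            vals = isl_field[inside[0] - r0, inside[1] - c0]
            thresh = np.partition(vals, -k)[-k]
            sel = vals >= thresh
            fire_islands[inside[0][sel], inside[1][sel]] = True

        # overlapping fires keep the most recent burn year per cell
        newer = fire_mask & ((burn == BURN_NODATA) | (fire_year > burn))
        burn[newer] = fire_year
        islands[fire_mask] = False  # a reburn erases older islands
        islands |= fire_islands
        perimeters.append((mask_to_polygons(fire_mask, elevation), fire_year))

    burn_year = RasterGrid(burn, cs, origin, nodata=BURN_NODATA)
    island_mask = RasterGrid(islands, cs, origin, nodata=0)

    # cheatgrass percent cover on the coarse grid: skewed-low cover that
    # declines with elevation, as the invasion is climate-limited upslope
    ccs = config.cheat_cell_size_m
    c_nrows = max(int(math.ceil(config.extent_m[1] / ccs)), 1)
    c_ncols = max(int(math.ceil(config.extent_m[0] / ccs)), 1)
    c_field = _smooth_field(rng, (c_nrows, c_ncols), sigma=max(c_nrows, c_ncols) / 8)
    # block-average elevation onto the coarse grid for the downslope bias
    zoom_r = nrows / c_nrows
    zoom_c = ncols / c_ncols
    r_idx = np.minimum((np.arange(c_nrows) * zoom_r).astype(int), nrows - 1)
    c_idx = np.minimum((np.arange(c_ncols) * zoom_c).astype(int), ncols - 1)
    elev_coarse = elev[np.ix_(r_idx, c_idx)]
    elev01 = (elev_coarse - lo) / max(hi - lo, 1.0)
    logit = -1.5 + 1.2 * c_field - 3.0 * elev01
    cover = 100.0 / (1.0 + np.exp(-logit))
    cheatgrass = RasterGrid(cover, ccs, origin)

    return SyntheticLandscape(
        config=config,
        fire_history=FireHistoryLayers(burn_year, island_mask, perimeters),
        veg_type=veg_type,
        height_class=height_class,
        elevation=elevation,
        cheatgrass=cheatgrass,
    )


def simulate_lek_counts(
    params: TrueLekParams,
    rng: np.random.Generator,
    *,
    fire_year_is_post: bool = True,
) -> "pd.DataFrame":
    """Draw one Poisson count per survey year from the log-linear model.

    X1 is the survey year centered at the fire year (or at the first survey
    year when the lek has no fire), and X2 = 1 for years at or after the
    fire year (``fire_year_is_post=False`` makes the fire year itself
    prefire instead).

    Returns a DataFrame with columns lek_id, x, y, year, males.

    Raises
    ------
    ValueError
        If any |linear predictor| exceeds 30 (the Poisson mean would
        overflow or underflow meaningfully).
    """
    import pandas as pd

    years = np.asarray(params.survey_years, dtype=float)
    center = float(params.fire_year) if params.fire_year is not None else years[0]
    x1 = years - center
    if params.fire_year is None:
        x2 = np.zeros_like(x1)
    elif fire_year_is_post:
        x2 = (years >= params.fire_year).astype(float)
    else:
        x2 = (years > params.fire_year).astype(float)
    eta = params.beta0 + params.beta1 * x1 + params.beta2 * x2 + params.beta3 * x1 * x2
    if np.any(np.abs(eta) > 30):
        worst = float(np.max(np.abs(eta)))
        raise ValueError(
            f"linear predictor magnitude {worst:.1f} exceeds 30 for lek "
            f"{params.lek_id}; the Poisson mean is not representable"
        )
    counts = rng.poisson(np.exp(eta))
    return pd.DataFrame(
        {
            "lek_id": params.lek_id,
            "x": params.x,
            "y": params.y,
            "year": np.asarray(params.survey_years, dtype=int),
            "males": counts,
        }
    )


def place_leks(
    landscape: SyntheticLandscape,
    rng: np.random.Generator,
    n_per_category: int = 3,
    *,
    edge_margin_m: float = 60.0,
    inner_margin_m: float = 0.0,
    max_tries: int = 20_000,
) -> "pd.DataFrame":
    """Plant lek points with known fire context in all four categories.

    Placement uses vector distances to the synthetic perimeters, so planted
    labels can be compared against the classifier's output exactly:

    - ``unburned_island``: cell centers of island cells at least
      ``edge_margin_m`` inside the island patch edge;
    - ``fire_perimeter``: burned (non-island) interior cells at least
      ``edge_margin_m`` from both the perimeter and any island;
    - ``small_buffer`` / ``large_buffer``: rejection-sampled points whose
      distance to the nearest perimeter falls well inside (0.05, 1.5) km
      and (1.5, 6.4) km respectively.

    ``inner_margin_m`` keeps every lek at least that far from the raster
    edge, so that later disc extractions (up to 18 km radius) stay inside
    the grid.

    Returns a DataFrame with columns lek_id, x, y, category, fire_year;
    categories that cannot be filled on the given landscape are returned
    with fewer (possibly zero) rows.
    """
    import pandas as pd

    fh = landscape.fire_history
    grid = fh.burn_year
    xmin, ymin, xmax, ymax = grid.extent
    xmin += inner_margin_m
    ymin += inner_margin_m
    xmax -= inner_margin_m
    ymax -= inner_margin_m
    if xmin >= xmax or ymin >= ymax:
        raise ValueError("inner_margin_m leaves no room for lek placement")
    all_perims = union_all([p for p, _ in fh.perimeters])
    island_poly = mask_to_polygons(fh.island_mask.data.astype(bool), grid)

    from shapely import Point

    rows: list[dict] = []

    def nearest_fire_year(x: float, y: float) -> int | None:
        best, best_d = None, np.inf
        pt = Point(x, y)
        for poly, yr in fh.perimeters:
            d = poly.distance(pt)
            if d < best_d - 1e-9 or (abs(d - best_d) <= 1e-9 and best is not None and yr < best):
                best, best_d = yr, d
        return best

    # island and burned-interior leks from qualifying cell centers; leks
    # only occur in sagebrush vegetation
    X, Y = grid.cell_centers()
    sage = landscape.veg_type.data == VEG_SAGEBRUSH
    isl = fh.island_mask.data.astype(bool) & sage
    burned = grid.data != BURN_NODATA

    def sample_cells(mask: np.ndarray, want: int, qualify) -> list[tuple[float, float]]:
        rr, cc = np.nonzero(mask)
        if rr.size == 0:
            return []
        order = rng.permutation(rr.size)[:max_tries]
        out = []
        for i in order:
            x, y = float(X[rr[i], cc[i]]), float(Y[rr[i], cc[i]])
            if qualify(x, y):
                out.append((x, y))
                if len(out) == want:
                    break
        return out

    def in_bounds(x: float, y: float) -> bool:
        return xmin <= x <= xmax and ymin <= y <= ymax

    def deep_in_island(x: float, y: float) -> bool:
        pt = Point(x, y)
        return (
            in_bounds(x, y)
            and island_poly.contains(pt)
            and island_poly.boundary.distance(pt) > edge_margin_m
        )

    def deep_in_burn(x: float, y: float) -> bool:
        pt = Point(x, y)
        return (
            in_bounds(x, y)
            and all_perims.contains(pt)
            and all_perims.boundary.distance(pt) > edge_margin_m
            and (island_poly.is_empty or island_poly.distance(pt) > edge_margin_m)
        )

    for x, y in sample_cells(isl, n_per_category, deep_in_island):
        rows.append(
            {"x": x, "y": y, "category": "unburned_island", "fire_year": nearest_fire_year(x, y)}
        )
    for x, y in sample_cells(burned & sage & ~fh.island_mask.data.astype(bool),
                             n_per_category, deep_in_burn):
        rows.append(
            {"x": x, "y": y, "category": "fire_perimeter", "fire_year": nearest_fire_year(x, y)}
        )

    # buffer leks: a raster distance transform proposes candidate cells in
    # the right distance band; the vector distance confirms each candidate
    if not all_perims.is_empty:
        cs = grid.cell_size
        dist = ndimage.distance_transform_edt(~burned, sampling=cs)
        margin = edge_margin_m
        bands = {
            "small_buffer": (50.0 + margin, 1_500.0 - margin),
            "large_buffer": (1_500.0 + margin, 6_400.0 - margin),
        }
        for cat, (lo_d, hi_d) in bands.items():
            cand = (dist > lo_d) & (dist < hi_d) & sage

            def in_band(x: float, y: float, lo_d=lo_d, hi_d=hi_d) -> bool:
                if not in_bounds(x, y):
                    return False
                d = all_perims.distance(Point(x, y))
                return lo_d < d < hi_d

            for x, y in sample_cells(cand, n_per_category, in_band):
                rows.append(
                    {"x": x, "y": y, "category": cat, "fire_year": nearest_fire_year(x, y)}
                )

    df = pd.DataFrame(rows, columns=["x", "y", "category", "fire_year"])
    df.insert(0, "lek_id", [f"lek_{i:03d}" for i in range(len(df))])
    return df
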