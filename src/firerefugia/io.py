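"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: lek counts and result tables as CSV, fire
perimeters as GeoJSON (with a ``fire_year`` property per feature), rasters
as ESRI ASCII grids.  All geometries live in one planar CRS in meters;
grids that disagree in origin or cell size are an error, never silently
reprojected.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import RasterGrid, read_ascii_grid  # noqa: F401  (re-exported)
from .trends import LekSurveySeries

__all__ = [
    "read_lek_counts",
    "write_lek_counts",
    "read_perimeters_geojson",
    "write_perimeters_geojson",
    "counts_to_series",
    "read_ascii_grid",
]

COUNT_COLUMNS = ["lek_id", "x", "y", "year", "males"]


def read_lek_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lek count table missing columns: {missing}")
    return df


def write_lek_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=[c for c in COUNT_COLUMNS if c in df.columns])


def write_perimeters_geojson(
    perimeters: list[tuple[BaseGeometry, int]], path: str | Path
) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"fire_year": int(year)},
            "geometry": mapping(poly),
        }
        for poly, year in perimeters
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_perimeters_geojson(path: str | Path) -> list[tuple[BaseGeometry, int]]:
    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if "fire_year" not in props:
            raise ValueError("perimeter feature missing fire_year property")
        out.append((shape(feat["geometry"]), int(props["fire_year"])))
    return out


def counts_to_series(
    counts: pd.DataFrame, fire_years: dict[str, int]
) -> list[LekSurveySeries]:
    """Group a long count table into per-lek series with their fire years.

    Leks absent from ``fire_years`` (no fire within analysis range) are
    skipped; duplicate (lek, year) rows are an error.
    """
    out = []
    for lek_id, sub in counts.groupby("lek_id", sort=True):
        if lek_id not in fire_years or fire_years[lek_id] is None:
            continue
        sub = sub.sort_values("year")
        if sub["year"].duplicated().any():
            raise ValueError(f"duplicate survey year for lek {lek_id}")
        out.append(
            LekSurveySeries(
                lek_id=str(lek_id),
                years=sub["year"].to_numpy(),
                males=sub["males"].to_numpy(),
                fire_year=int(fire_years[lek_id]),
            )
        )
    return out
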