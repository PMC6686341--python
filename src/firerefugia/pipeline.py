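"""End-to-end orchestration: simulate -> classify -> trends -> compare ->
habitat -> multimodel inference.

The pipeline runs either on files (counts CSV, GeoJSON perimeters, ASCII
grids) or on a fully synthetic landscape described by the config's
``synthetic`` block.  Every stage writes its table under the output
directory and a JSON manifest records the seed, a hash of the resolved
config, and per-stage record counts, so a run is auditable and two runs
with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import habitat as _habitat
from .compare import compare_pre_post
from .grid import RasterGrid
from .io import write_lek_counts, write_perimeters_geojson
from .multimodel import run_model_selection
from .synthetic import (
    LandscapeConfig,
    SyntheticLandscape,
    TrueLekParams,
    generate_landscape,
    place_leks,
    simulate_lek_counts,
)
from .trends import LekSurveySeries, filter_leks, fit_prepost_glm

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

#: per-category true trend parameters of the synthetic study conditions:
#: burned leks crash after fire, small-buffer leks dip, island and
#: large-buffer (control) leks stay roughly stable.
CATEGORY_TRENDS = {
    "unburned_island": {"beta1": 0.02, "beta2": -0.10, "beta3": -0.01},
    "fire_perimeter": {"beta1": 0.03, "beta2": -0.70, "beta3": -0.20},
    "small_buffer": {"beta1": 0.02, "beta2": -0.20, "beta3": -0.06},
    "large_buffer": {"beta1": 0.01, "beta2": 0.00, "beta3": 0.00},
}


@dataclass
class Thresholds:
    """Every fixed analysis constant in one auditable place."""

    island_near_m: float = 50.0
    small_buffer_max_m: float = 1_500.0
    large_buffer_max_m: float = 6_400.0
    radii_m: tuple[float, float, float] = (800.0, 6_400.0, 18_000.0)
    cheat_cover_pct: float = 8.0
    cheat_elevation_m: float = 2_000.0
    lookback_years: int = 17
    min_survey_years: int = 6

    def __post_init__(self) -> None:
        for name in ("island_near_m", "small_buffer_max_m", "large_buffer_max_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        r = tuple(self.radii_m)
        if len(r) != 3 or not (0 < r[0] < r[1] < r[2]):
            raise ValueError("radii_m must be three strictly increasing positive values")
        self.radii_m = r


@dataclass
class SyntheticBlock:
    """Synthetic-input description: a landscape plus lek/count design."""

    landscape: LandscapeConfig = field(
        default_factory=lambda: LandscapeConfig(
            extent_m=(60_000.0, 60_000.0), n_fires=24, rng_seed=0
        )
    )
    n_leks_per_category: int = 8
    count_years: tuple[int, int] = (1984, 2017)
    survey_prob: float = 0.8  # leks are not surveyed every year
    base_log_count: float = 3.5  # ~33 males at the fire year
    fire_year_is_post: bool = True

    def __post_init__(self) -> None:
        if self.n_leks_per_category < 1:
            raise ValueError("n_leks_per_category must be >= 1")
        if self.count_years[1] <= self.count_years[0]:
            raise ValueError("count_years must span at least 2 years")


@dataclass
class PipelineConfig:
    seed: int = 0
    averaging: str = "full"
    out_dir: str = "results"
    thresholds: Thresholds = field(default_factory=Thresholds)
    synthetic: SyntheticBlock = field(default_factory=SyntheticBlock)

    def __post_init__(self) -> None:
        if self.averaging not in ("full", "conditional"):
            raise ValueError("averaging must be 'full' or 'conditional'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)

        def build(klass, sub: dict):
            allowed = set(klass.__dataclass_fields__)
            unknown = set(sub) - allowed
            if unknown:
                raise ValueError(f"unknown config keys for {klass.__name__}: {sorted(unknown)}")
            fixed = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
            }
            return klass(**fixed)

        if "thresholds" in d:
            d["thresholds"] = build(Thresholds, d["thresholds"])
        if "synthetic" in d:
            sub = dict(d["synthetic"])
            if "landscape" in sub:
                sub["landscape"] = build(LandscapeConfig, sub["landscape"])
            d["synthetic"] = build(SyntheticBlock, sub)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    landscape: SyntheticLandscape
    leks: pd.DataFrame
    counts: pd.DataFrame
    assignments: pd.DataFrame
    trend_table: pd.DataFrame
    comparisons: pd.DataFrame
    covariates: pd.DataFrame
    model_table: pd.DataFrame
    averaged: pd.DataFrame
    manifest: dict


def _simulate_inputs(cfg: PipelineConfig) -> tuple[SyntheticLandscape, pd.DataFrame, pd.DataFrame]:
    """Generate landscape, leks and count series with known ground truth.

    The true postfire trend change of each lek combines its category's base
    value with mild habitat dependence — higher elevation helps, local
    cheatgrass cover hurts — so the inference stage has a real signal to
    recover.
    """
    syn = cfg.synthetic
    # cfg.seed is the single source of randomness: it re-seeds the
    # landscape and drives lek placement and count simulation
    land_seed = int(np.random.SeedSequence([cfg.seed, 0]).generate_state(1)[0] % 2**31)
    land = generate_landscape(replace(syn.landscape, rng_seed=land_seed))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    margin = cfg.thresholds.radii_m[-1] + 2 * land.elevation.cell_size
    leks = place_leks(
        land, rng, syn.n_leks_per_category, inner_margin_m=margin
    )
    if leks.empty:
        raise RuntimeError("synthetic landscape produced no placeable leks")

    elev_at = np.array([land.elevation.value_at(r.x, r.y) for r in leks.itertuples()])
    cheat_at = np.array([land.cheatgrass.value_at(r.x, r.y) for r in leks.itertuples()])
    z = lambda v: (v - v.mean()) / v.std() if v.std() > 0 else np.zeros_like(v)
    z_elev, z_cheat = z(elev_at), z(cheat_at)

    y0, y1 = syn.count_years
    all_counts = []
    true_rows = []
    for i, row in enumerate(leks.itertuples()):
        base = CATEGORY_TRENDS[row.category]
        fy = int(row.fire_year) if row.fire_year is not None else (y0 + y1) // 2
        beta0 = syn.base_log_count + rng.normal(0, 0.25)
        beta1 = base["beta1"] + rng.normal(0, 0.01)
        beta3 = (
            base["beta3"] + 0.03 * z_elev[i] - 0.03 * z_cheat[i] + rng.normal(0, 0.01)
        )
        candidates = np.arange(y0, y1 + 1)
        surveyed = rng.random(candidates.size) < syn.survey_prob
        years = tuple(int(v) for v in candidates[surveyed])
        if not years:
            years = (fy,)
        params = TrueLekParams(
            lek_id=str(row.lek_id), x=float(row.x), y=float(row.y),
            beta0=beta0, beta1=beta1, beta3=beta3, beta2=base["beta2"],
            fire_year=fy, survey_years=years,
        )
        all_counts.append(
            simulate_lek_counts(params, rng, fire_year_is_post=syn.fire_year_is_post)
        )
        true_rows.append(
            {"lek_id": params.lek_id, "true_beta1": beta1, "true_beta3": beta3,
             "fire_year": fy, "category": row.category}
        )
    counts = pd.concat(all_counts, ignore_index=True)
    leks = leks.merge(pd.DataFrame(true_rows)[["lek_id", "true_beta1", "true_beta3"]], on="lek_id")
    return land, leks, counts


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None,
                 *, write_outputs: bool = True, write_figures: bool = False) -> PipelineResult:
    """Execute all stages in order and (optionally) write every output.

    Any stage failure raises with the stage name (and lek id where
    applicable) so a broken run is never silently partial.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    hashed = cfg.to_dict()
    hashed.pop("out_dir", None)  # the output location is not an analysis condition
    manifest: dict = {
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(hashed, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }

    stage = "simulate"
    try:
        land, leks, counts = _simulate_inputs(cfg)
        manifest["stages"][stage] = {"leks": int(len(leks)), "count_rows": int(len(counts))}

        stage = "classify"
        assignments = _classify.classify_leks(
            leks[["lek_id", "x", "y"]], land.fire_history,
            island_near_m=th.island_near_m,
            small_buffer_max_m=th.small_buffer_max_m,
            large_buffer_max_m=th.large_buffer_max_m,
        )
        manifest["stages"][stage] = {"classified": int(len(assignments))}

        stage = "trends"
        fire_years = {
            r.lek_id: int(r.burn_year) for r in assignments.itertuples()
            if not pd.isna(r.burn_year)
        }
        categories = {r.lek_id: r.category for r in assignments.itertuples()}
        series = []
        for lek_id, sub in counts.groupby("lek_id", sort=True):
            if lek_id not in fire_years:
                continue
            sub = sub.sort_values("year")
            series.append(LekSurveySeries(str(lek_id), sub["year"].to_numpy(),
                                          sub["males"].to_numpy(), fire_years[str(lek_id)]))
        included, reasons = filter_leks(
            series, categories, min_survey_years=th.min_survey_years,
            fire_year_is_post=cfg.synthetic.fire_year_is_post,
        )
        fits = [fit_prepost_glm(s, fire_year_is_post=cfg.synthetic.fire_year_is_post)
                for s in included]
        trend_table = pd.DataFrame(
            {
                "lek_id": [f.lek_id for f in fits],
                "category": [categories[f.lek_id] for f in fits],
                "beta0": [f.beta[0] for f in fits],
                "beta1": [f.beta[1] for f in fits],
                "beta2": [f.beta[2] for f in fits],
                "beta3": [f.beta[3] for f in fits],
                "se_beta1": [f.se[1] for f in fits],
                "se_beta3": [f.se[3] for f in fits],
                "pre_slope": [f.pre_slope for f in fits],
                "post_slope": [f.post_slope for f in fits],
                "converged": [f.converged for f in fits],
                "n_obs": [f.n_obs for f in fits],
            }
        )
        manifest["stages"][stage] = {
            "series": int(len(series)),
            "included": int(len(included)),
            "excluded": {k: sum(1 for v in reasons.values() if v == k) for k in "abcd"},
        }

        stage = "compare"
        comp_rows = []
        usable = trend_table[np.isfinite(trend_table["post_slope"])]
        for cat, sub in usable.groupby("category"):
            if len(sub) < 3:
                logger.info("category %s has %d usable leks; comparison skipped", cat, len(sub))
                continue
            c = compare_pre_post(sub["pre_slope"].to_numpy(), sub["post_slope"].to_numpy(),
                                 category=cat)
            comp_rows.append(
                {"category": cat, "n_leks": c.n_leks, "test": c.test_used.value,
                 "statistic": c.statistic, "df": c.df, "p_value": c.p_value,
                 "mean_pre": float(np.mean(c.pre_slopes)),
                 "mean_post": float(np.mean(c.post_slopes))}
            )
        comparisons = pd.DataFrame(comp_rows)
        manifest["stages"][stage] = {"categories_tested": int(len(comparisons))}

        stage = "habitat"
        cov_rows = []
        fh = land.fire_history
        surfaces_cache: dict[int, _habitat.PostfireSurfaces] = {}
        lek_xy = {r.lek_id: (float(r.x), float(r.y)) for r in leks.itertuples()}
        for r in usable.itertuples():
            fy = fire_years[r.lek_id]
            if fy not in surfaces_cache:
                surfaces_cache[fy] = _habitat.build_surfaces(
                    fy, fh.burn_year, land.height_class, land.veg_type,
                    land.cheatgrass, land.elevation,
                    lookback_years=th.lookback_years,
                    cover_threshold_pct=th.cheat_cover_pct,
                    elevation_threshold_m=th.cheat_elevation_m,
                )
            hc = _habitat.extract_covariates(
                r.lek_id, lek_xy[r.lek_id], fy, surfaces_cache[fy], radii_m=th.radii_m
            )
            cov_rows.append(
                {
                    "lek_id": hc.lek_id, "fire_year": hc.fire_year,
                    "veg_height_0.8km": hc.veg_height[0],
                    "veg_height_6.4km": hc.veg_height[1],
                    "veg_height_18km": hc.veg_height[2],
                    "cheat_frac_0.8km": hc.cheat_frac[0],
                    "cheat_frac_6.4km": hc.cheat_frac[1],
                    "cheat_frac_18km": hc.cheat_frac[2],
                    "elevation_0.8km": hc.elevation[0],
                    "elevation_6.4km": hc.elevation[1],
                    "elevation_18km": hc.elevation[2],
                }
            )
        covariates = pd.DataFrame(cov_rows)
        manifest["stages"][stage] = {"leks_with_covariates": int(len(covariates))}

        stage = "infer"
        merged = usable.merge(covariates, on="lek_id")
        pred_cols = [c for c in covariates.columns if c not in ("lek_id", "fire_year")]
        X = merged[pred_cols].rename(
            columns=lambda c: c.replace("0.8km", "0.8").replace("6.4km", "6.4").replace("18km", "18")
        )
        model_table, avg, _fitted = run_model_selection(
            merged["post_slope"].to_numpy(), X,
            variables=["veg_height", "cheat_frac", "elevation"],
            scales=["0.8", "6.4", "18"],
            mode=cfg.averaging,
        )
        averaged = avg.table.reset_index(names="predictor")
        manifest["stages"][stage] = {
            "n_models": int(avg.n_models), "n_leks": int(len(merged)),
        }
    except Exception as exc:  # annotate with the failing stage, then re-raise
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    if write_outputs:
        write_lek_counts(counts, out / "lek_counts.csv")
        leks.to_csv(out / "leks_true.csv", index=False)
        write_perimeters_geojson(fh.perimeters, out / "perimeters.geojson")
        assignments.to_csv(out / "assignments.csv", index=False)
        trend_table.to_csv(out / "trend_fits.csv", index=False)
        comparisons.to_csv(out / "category_comparisons.csv", index=False)
        covariates.to_csv(out / "habitat_covariates.csv", index=False)
        model_table.to_csv(out / "model_table.csv", index=False)
        averaged.to_csv(out / "averaged_coefficients.csv", index=False)
        with open(out / "manifest.json", "w") as fhj:
            json.dump(manifest, fhj, indent=2, sort_keys=True)
        if write_figures:
            from .plots import plot_averaged_coefficients, plot_category_boxplots

            if not comparisons.empty:
                plot_category_boxplots(comparisons, trend_table, out / "category_boxplots.png")
            plot_averaged_coefficients(averaged, out / "averaged_coefficients.png")

    return PipelineResult(
        landscape=land, leks=leks, counts=counts, assignments=assignments,
        trend_table=trend_table, comparisons=comparisons, covariates=covariates,
        model_table=model_table, averaged=averaged, manifest=manifest,
    )
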