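"""End-to-end orchestration: synthetic city -> LUR -> diurnal -> exposure.

One :class:`RunConfig` (loadable from YAML) drives every stage; a single
master seed deterministically derives each stage's random stream, so the
same config + seed reproduce every artifact byte for byte. Artifacts are
written as plain-text formats (ESRI ASCII grids, CSV, GeoJSON, JSON) and a
run manifest records each file with its SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import buffers, diurnal, exposure, lur, population, synthetic
from .raster import GridRaster, write_ascii_grid

logger = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.10g"
ALL_PERIODS = ("spring", "summer", "autumn", "winter", "yearly")


@dataclass
class RunConfig:
    """Validated run settings for the pipeline."""

    city: synthetic.CityConfig = field(default_factory=synthetic.CityConfig)
    lur: lur.LURConfig = field(default_factory=lur.LURConfig)
    ladder_max_radius_m: float = 5010.0
    ladder_exhaustive: bool = False
    day_hour: int = 15
    night_hour: int = 2
    outdir: Path = Path("lurex_run")
    seed: int = 0
    census_coarsen: int = 10  # census raster cell = this many map cells

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not (0 <= self.day_hour < 24 and 0 <= self.night_hour < 24):
            raise ValueError("day/night hours must be in 0..23")
        if self.census_coarsen < 1:
            raise ValueError("census_coarsen must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "city" not in raw:
            raise ValueError(
                "config must contain a 'city' synthetic block (real-input "
                "paths are configured per stage)")
        city_raw = dict(raw.pop("city") or {})
        if "true_model" in city_raw:
            tm = city_raw["true_model"]
            city_raw["true_model"] = synthetic.TrueModel(
                intercept=float(tm["intercept"]),
                terms=tuple((t["covariate"], float(t["radius_m"]),
                             float(t["coefficient"])) for t in tm["terms"]),
                season=tm.get("season", "yearly"))
        lur_raw = dict(raw.pop("lur", {}) or {})
        return cls(city=synthetic.CityConfig(**city_raw),
                   lur=lur.LURConfig(**lur_raw), **raw)


def seasonal_site_means(cleaned: pd.DataFrame,
                        periods=ALL_PERIODS) -> dict[str, pd.DataFrame]:
    """Observed mean PM2.5 per site for each season and for the year.

    Returns per period a DataFrame with columns site_id, x, y, pm25.
    """
    out: dict[str, pd.DataFrame] = {}
    for period in periods:
        sub = cleaned if period == "yearly" else cleaned[cleaned["season"] == period]
        g = (sub.groupby(["site_id", "x", "y"], as_index=False)["pm25"]
             .mean().sort_values("site_id", ignore_index=True))
        out[period] = g
    return out


def fit_period_model(covariates: dict[str, GridRaster],
                     site_means: pd.DataFrame,
                     ladder: buffers.BufferLadder,
                     config: lur.LURConfig,
                     period: str
                     ) -> tuple[lur.LURModel, pd.DataFrame, dict[str, float],
                                pd.DataFrame]:
    """Buffer search + stepwise LUR + LOOCV for one averaging period.

    Returns the fitted model (diagnostics filled in), the feature table,
    the chosen per-covariate radii and the full (covariate, radius, r)
    scan kept as the audit trail of the buffer search.
    """
    response = site_means["pm25"].to_numpy()
    xs, ys = site_means["x"].to_numpy(), site_means["y"].to_numpy()
    chosen: dict[str, float] = {}
    scans = []
    for name, raster in covariates.items():
        scan = buffers.buffer_scan(raster, xs, ys, response, ladder)
        chosen[name] = buffers.optimal_from_scan(scan, name)[0]
        scans.append(scan.assign(covariate=name))
    scan_table = pd.concat(scans, ignore_index=True)[
        ["covariate", "radius_m", "r"]]
    features = buffers.build_feature_table(covariates, chosen, site_means,
                                           response)
    model = lur.stepwise_select(features, config, season=period)
    if model.terms:
        model.diagnostics.update(lur.loocv(features, model))
    return model, features, chosen, scan_table


def census_raster_from_homes(city: synthetic.SyntheticCity,
                             coarsen: int) -> GridRaster:
    """Static residential-population raster from agents' home stations.

    Home counts are binned onto a grid ``coarsen`` times coarser than the
    analysis grid, emulating a coarse census product that is later
    nearest-neighbor resampled onto the map.
    """
    ref = next(iter(city.covariates.values()))
    cs = ref.cell_size_m * coarsen
    nrows = int(np.ceil(ref.nrows / coarsen))
    ncols = int(np.ceil(ref.ncols / coarsen))
    homes = np.bincount(city.agents.home_station,
                        minlength=len(city.stations)).astype(float)
    xs = city.stations["x"].to_numpy()
    ys = city.stations["y"].to_numpy()
    cols = np.minimum((xs / cs).astype(int), ncols - 1)
    rows = nrows - 1 - np.minimum((ys / cs).astype(int), nrows - 1)
    grid = np.zeros((nrows, ncols))
    np.add.at(grid, (rows, cols), homes)
    return GridRaster(grid, x_origin=ref.x_origin, y_origin=ref.y_origin,
                      cell_size_m=cs, units="persons", name="census")


@dataclass
class PipelineResult:
    """In-memory results of a full run."""

    city: synthetic.SyntheticCity
    cleaned: pd.DataFrame
    drop_report: diurnal.DropReport
    models: dict[str, lur.LURModel]
    features: dict[str, pd.DataFrame]
    scans: dict[str, pd.DataFrame]
    surfaces: dict[str, GridRaster]
    factors: dict[str, diurnal.AdjustmentFactors]
    weights: population.PopulationWeights
    commute: population.CommuteTable
    series: dict[str, exposure.ExposureSeries]
    curves: dict[int, exposure.ExposureCurve]
    comparison: exposure.ComparisonTable


def run_stages(config: RunConfig) -> PipelineResult:
    """Execute every stage in memory and return the results bundle."""
    city_cfg = config.city
    if config.seed is not None:
        from dataclasses import replace
        city_cfg = replace(city_cfg, rng_seed=config.seed)
    city = synthetic.generate_city(city_cfg, seed=config.seed)

    periods = (*city_cfg.seasons, "yearly")
    cleaned, report = diurnal.clean_observations(city.observations)
    means = seasonal_site_means(cleaned, periods)
    ladder = buffers.default_ladder(config.ladder_max_radius_m,
                                    step_m=max(30.0, city_cfg.cell_size_m / 3),
                                    exhaustive=config.ladder_exhaustive,
                                    min_radius_m=city_cfg.cell_size_m / 2)

    models: dict[str, lur.LURModel] = {}
    features: dict[str, pd.DataFrame] = {}
    scans: dict[str, pd.DataFrame] = {}
    surfaces: dict[str, GridRaster] = {}
    for period in periods:
        model, feats, _, scan = fit_period_model(
            city.covariates, means[period], ladder, config.lur, period)
        models[period] = model
        features[period] = feats
        scans[period] = scan
        surfaces[period] = lur.predict_surface(model, city.covariates)

    factors = {
        p: diurnal.adjustment_factors(diurnal.diurnal_profile(cleaned, p))
        for p in periods
    }

    weights = population.standardize_counts(city.counts)
    commute = population.commute_net_change(weights, city.rings,
                                            config.day_hour, config.night_hour)

    series = {
        "commute_only": exposure.hourly_exposure_series(
            surfaces["yearly"], weights, "commute_only"),
        "combined": exposure.hourly_exposure_series(
            surfaces["yearly"], weights, "combined",
            factors=factors["yearly"]),
    }
    conc = exposure.extract_at_points(surfaces["yearly"], weights.x, weights.y)
    curves = {
        h: exposure.exposure_curve(conc, weights.column(h), hour=h)
        for h in (config.night_hour, config.day_hour)
    }
    census = census_raster_from_homes(city, config.census_coarsen)
    comparison = exposure.compare_measures(
        means["yearly"].rename(columns={"pm25": "pm25"}),
        surfaces["yearly"], census, weights,
        reference_site_id=str(means["yearly"]["site_id"].iloc[0]))
    return PipelineResult(city=city, cleaned=cleaned, drop_report=report,
                          models=models, features=features, scans=scans,
                          surfaces=surfaces, factors=factors,
                          weights=weights, commute=commute, series=series,
                          curves=curves, comparison=comparison)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_artifacts(result: PipelineResult, config: RunConfig,
                    stages: set[str] | None = None) -> dict:
    """Write stage artifacts and return the run manifest."""
    stages = stages or {"simulate", "lur", "diurnal", "population", "exposure"}
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format=CSV_FLOAT_FORMAT)
        written.append(p)

    city = result.city
    if "simulate" in stages:
        for name, raster in city.covariates.items():
            written.append(write_ascii_grid(raster, out / f"cov_{name}.asc"))
        for period, raster in city.truths.items():
            written.append(write_ascii_grid(raster, out / f"truth_{period}.asc"))
        save_df(city.sites, "sites.csv")
        save_df(city.observations, "observations.csv")
        save_df(city.counts.to_frame(), "station_counts.csv")
        written.append(city.rings.to_geojson(out / "rings.geojson"))
        cfg_dict = {
            "domain_size_m": list(city.config.domain_size_m),
            "cell_size_m": city.config.cell_size_m,
            "n_sites": city.config.n_sites,
            "n_stations": city.config.n_stations,
            "n_agents": city.config.n_agents,
            "seasons": list(city.config.seasons),
            "rng_seed": city.config.rng_seed,
            "noise_sd_ugm3": city.config.noise_sd_ugm3,
            "outlier_fraction": city.config.outlier_fraction,
            "missing_fraction": city.config.missing_fraction,
            "n_days_per_season": city.config.n_days_per_season,
            "commuter_fraction": city.config.commuter_fraction,
            "ring_radii_m": list(city.config.ring_radii_m),
            "phone_on_prob": [float(p) for p in city.config.phone_on_prob],
            "diurnal_profiles": {k: [float(v) for v in prof] for k, prof
                                 in city.config.diurnal_profiles.items()},
        }
        p = out / "config.yaml"
        p.write_text(yaml.safe_dump({"city": cfg_dict, "seed": config.seed},
                                    sort_keys=True))
        written.append(p)
    if "lur" in stages:
        written.append(lur.save_models(list(result.models.values()),
                                       out / "lur_models.json"))
        for period in result.features:
            save_df(result.features[period].reset_index(),
                    f"features_{period}.csv")
            save_df(result.scans[period], f"buffer_scan_{period}.csv")
        for period, surf in result.surfaces.items():
            written.append(write_ascii_grid(surf, out / f"pm25_{period}.asc"))
    if "diurnal" in stages:
        save_df(diurnal.factors_frame(list(result.factors.values())),
                "adjustment_factors.csv")
    if "population" in stages:
        w = result.weights
        save_df(pd.DataFrame({
            "station_id": np.repeat(w.station_id, 24),
            "hour": np.tile(np.arange(24), w.weights.shape[0]),
            "weight": w.weights.ravel(),
        }), "population_weights.csv")
        save_df(result.commute.to_frame(), "commute_table.csv")
    if "exposure" in stages:
        save_df(pd.concat([s.to_frame() for s in result.series.values()],
                          ignore_index=True), "exposure_series.csv")
        for h, curve in result.curves.items():
            save_df(pd.DataFrame({"pm25": curve.breakpoints,
                                  "cum_fraction": curve.cum_fraction}),
                    f"exposure_curve_h{h:02d}.csv")
        save_df(result.comparison.to_frame(), "exposure_comparison.csv")
        summary = {
            "drop_report": vars(result.drop_report),
            "commute": result.commute.entries,
            "comparison": {k: v for k, v in
                           zip(result.comparison.to_frame()["measure"],
                               result.comparison.to_frame()["exposure_ugm3"])},
            "models": {p: m.to_dict() for p, m in result.models.items()},
        }
        p = out / "summary.json"
        p.write_text(json.dumps(summary, indent=1, default=float))
        written.append(p)

    manifest = {
        "seed": config.seed,
        "stages": sorted(stages),
        "artifacts": {str(p.relative_to(out)): _sha256(p)
                      for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def run_pipeline(config: RunConfig,
                 stages: set[str] | None = None) -> dict:
    """Run the full pipeline and write artifacts; returns the manifest.

    Any stage failure is re-raised annotated with the stage name.
    """
    try:
        result = run_stages(config)
    except Exception as exc:  # annotate for the CLI
        raise RuntimeError(f"pipeline failed during computation: {exc}") from exc
    return write_artifacts(result, config, stages)
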