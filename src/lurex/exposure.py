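"""Population-weighted exposure statistics.

Exposure combines where the pollution is with where the people are: the
concentration map is sampled at the base stations and averaged with the
standardized device counts as weights. Two decompositions are reported:

* ``commute_only`` — one fixed (seasonal/yearly) map for all hours, so the
  hourly variation of the series is caused solely by people moving;
* ``combined`` — the diurnally adjusted hourly maps, so the series carries
  both the commute and the concentration cycle. Because hourly maps are the
  base map times a spatially uniform factor, combined[h] equals
  commute_only[h] x factor[h] exactly.

The module also builds population-weighted cumulative exposure curves and
the five-way comparison of common exposure measures (single reference
site, mean of all sites, map mean, census-weighted, mobile-weighted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diurnal import AdjustmentFactors
from .population import PopulationWeights
from .raster import GridRaster, extract_at_points, resample_nearest


def weighted_exposure(concentrations, weights) -> float:
    """Population-weighted mean concentration: sum(w*c)/sum(w)."""
    c = np.asarray(concentrations, float)
    w = np.asarray(weights, float)
    if c.shape != w.shape:
        raise ValueError("concentrations and weights must have equal length")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must have positive sum")
    return float(np.dot(w, c) / total)


@dataclass
class ExposureSeries:
    """24 hourly population-weighted mean concentrations (μg/m³)."""

    values: np.ndarray
    mode: str  # "commute_only" | "combined"
    label: str = "yearly"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (24,):
            raise ValueError("series must have exactly 24 hourly values")
        if self.mode not in ("commute_only", "combined"):
            raise ValueError("mode must be 'commute_only' or 'combined'")

    def __getitem__(self, hour: int) -> float:
        return float(self.values[hour])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hour": np.arange(24), "mode": self.mode,
                             "label": self.label, "exposure": self.values})


def hourly_exposure_series(base_map: GridRaster,
                           weights: PopulationWeights,
                           mode: str = "commute_only",
                           factors: AdjustmentFactors | None = None,
                           label: str = "yearly") -> ExposureSeries:
    """Hourly population-weighted exposure at the base stations.

    ``commute_only`` uses the fixed base map at every hour; ``combined``
    scales it by the hourly adjustment factors (equivalent to sampling the
    24 hourly maps) and requires ``factors``.
    """
    if mode == "combined" and factors is None:
        raise ValueError("combined mode requires hourly adjustment factors")
    conc = extract_at_points(base_map, weights.x, weights.y)
    if np.isnan(conc).any():
        raise ValueError("some stations fall on nodata map cells")
    out = np.empty(24)
    for h in range(24):
        e = weighted_exposure(conc, weights.column(h))
        if mode == "combined":
            e *= factors[h]
        out[h] = e
    return ExposureSeries(values=out, mode=mode, label=label)


@dataclass
class ExposureCurve:
    """Weighted cumulative exposure distribution for one hour.

    ``breakpoints`` are the sorted distinct station concentrations and
    ``cum_fraction[i]`` the population fraction exposed at or below
    ``breakpoints[i]``; nondecreasing and ending at 1.
    """

    breakpoints: np.ndarray
    cum_fraction: np.ndarray
    hour: int

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, float)
        self.cum_fraction = np.asarray(self.cum_fraction, float)
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(np.diff(self.cum_fraction) < -1e-12) or \
                abs(self.cum_fraction[-1] - 1.0) > 1e-9:
            raise ValueError("cumulative fractions must rise to 1")

    def fraction_at_or_below(self, c: float) -> float:
        """CDF evaluated at concentration ``c``."""
        idx = np.searchsorted(self.breakpoints, c, side="right") - 1
        return 0.0 if idx < 0 else float(self.cum_fraction[idx])

    def mean(self) -> float:
        """Weighted mean via the distribution (sum of c * probability mass)."""
        pmf = np.diff(np.concatenate([[0.0], self.cum_fraction]))
        return float(np.dot(self.breakpoints, pmf))


def exposure_curve(concentrations, weights, hour: int = 0) -> ExposureCurve:
    """Empirical population-weighted CDF of station concentrations."""
    c = np.asarray(concentrations, float)
    w = np.asarray(weights, float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    order = np.argsort(c, kind="stable")
    c, w = c[order], w[order]
    uniq, inverse = np.unique(c, return_inverse=True)
    mass = np.bincount(inverse, weights=w) / w.sum()
    return ExposureCurve(breakpoints=uniq, cum_fraction=np.cumsum(mass),
                         hour=hour)


def curves_cross(a: ExposureCurve, b: ExposureCurve) -> float | None:
    """Concentration where curve ``a`` stops lying above curve ``b``.

    Evaluates both CDFs on the union of breakpoints and returns the first
    concentration at which the sign of (a - b) flips from positive to
    negative (a genuine crossing), or None if the curves never cross.
    """
    grid = np.union1d(a.breakpoints, b.breakpoints)
    diff = np.array([a.fraction_at_or_below(c) - b.fraction_at_or_below(c)
                     for c in grid])
    seen_pos = False
    for c, d in zip(grid, diff):
        if d > 1e-12:
            seen_pos = True
        elif d < -1e-12 and seen_pos:
            return float(c)
    return None


@dataclass
class ComparisonTable:
    """The five common outdoor exposure measures, μg/m³."""

    reference_site: float
    mean_of_sites: float
    map_mean: float
    census_weighted: float
    mobile_weighted: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "measure": ["reference_site", "mean_of_sites", "map_mean",
                        "census_weighted", "mobile_weighted"],
            "exposure_ugm3": [self.reference_site, self.mean_of_sites,
                              self.map_mean, self.census_weighted,
                              self.mobile_weighted],
        })


def census_weighted_mean(pm_map: GridRaster, census: GridRaster) -> float:
    """Cellwise population-weighted map mean: sum(pop*pm)/sum(pop).

    The census raster is nearest-neighbor resampled onto the map grid when
    it is coarser; geometries must then match exactly.
    """
    if not census.same_geometry(pm_map):
        census = resample_nearest(census, pm_map)
    ok = pm_map.mask() & census.mask()
    if not ok.any():
        raise ValueError("no overlapping valid cells")
    pop = census.values[ok]
    if pop.sum() <= 0:
        raise ValueError("census population sums to zero")
    return float(np.dot(pop, pm_map.values[ok]) / pop.sum())


def compare_measures(site_means: pd.DataFrame, pm_map: GridRaster,
                     census: GridRaster, weights: PopulationWeights,
                     reference_site_id: str,
                     mobile_hour: int | None = None) -> ComparisonTable:
    """Build the five-way exposure-measure comparison.

    Parameters
    ----------
    site_means : DataFrame with columns ``site_id`` and ``pm25`` (observed
        mean concentration per monitoring site, μg/m³).
    pm_map : the LUR concentration surface.
    census : static residential population raster (resampled if coarser).
    weights : standardized hourly station weights; the mobile-weighted
        value uses their 24-hour day-average unless ``mobile_hour`` pins a
        single hour.
    reference_site_id : site standing in for a single urban reference
        monitor.
    """
    ref_rows = site_means.loc[site_means["site_id"] == reference_site_id, "pm25"]
    if ref_rows.empty:
        raise KeyError(f"reference site {reference_site_id!r} not found")
    conc = extract_at_points(pm_map, weights.x, weights.y)
    w = weights.column(mobile_hour) if mobile_hour is not None \
        else weights.day_average()
    return ComparisonTable(
        reference_site=float(ref_rows.iloc[0]),
        mean_of_sites=float(site_means["pm25"].mean()),
        map_mean=pm_map.mean(),
        census_weighted=census_weighted_mean(pm_map, census),
        mobile_weighted=weighted_exposure(conc, w),
    )
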