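"""Diurnal PM2.5 profiles and hourly adjustment of concentration maps.

LUR surfaces are most reliable for seasonal or yearly averages, so hourly
maps are obtained by scaling: the 24-hour mean concentration cycle is
computed from the cleaned site observations, divided by its daily mean to
give unitless hourly adjustment factors (mean exactly 1), and each factor
multiplies the seasonal (or yearly) base map. Because the factors average
to 1, the 24 hourly maps average cellwise back to the base map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import GridRaster

OUTLIER_THRESHOLD_UGM3 = 1000.0


@dataclass
class DropReport:
    """Counts of observations removed during cleaning, by cause."""

    n_input: int
    n_missing: int
    n_outlier: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_missing - self.n_outlier


def clean_observations(observations: pd.DataFrame,
                       threshold: float = OUTLIER_THRESHOLD_UGM3,
                       value_col: str = "pm25"
                       ) -> tuple[pd.DataFrame, DropReport]:
    """Drop missing values and gross outliers (strictly above ``threshold``
    μg/m³; a value exactly at the threshold is retained).

    Returns the cleaned frame and a report of drops by cause; dropping
    everything is an error.
    """
    n_input = len(observations)
    vals = observations[value_col]
    missing = vals.isna()
    outlier = vals > threshold
    keep = ~(missing | outlier)
    cleaned = observations[keep].copy()
    if cleaned.empty:
        raise ValueError("all observations dropped during cleaning")
    return cleaned, DropReport(n_input=n_input,
                               n_missing=int(missing.sum()),
                               n_outlier=int((outlier & ~missing).sum()))


@dataclass
class DiurnalProfile:
    """24 hourly mean concentrations (μg/m³) for one season, with counts."""

    season: str
    hourly_mean: np.ndarray
    hourly_count: np.ndarray

    def __post_init__(self) -> None:
        self.hourly_mean = np.asarray(self.hourly_mean, float)
        self.hourly_count = np.asarray(self.hourly_count, int)
        if self.hourly_mean.shape != (24,) or self.hourly_count.shape != (24,):
            raise ValueError("profile must have exactly 24 hourly entries")
        if (self.hourly_mean < 0).any():
            raise ValueError("hourly means must be nonnegative")

    @property
    def daily_mean(self) -> float:
        """Unweighted mean of the 24 hourly means."""
        return float(self.hourly_mean.mean())


def diurnal_profile(cleaned: pd.DataFrame, season: str,
                    value_col: str = "pm25") -> DiurnalProfile:
    """Pooled hourly mean concentration over all sites and days.

    Every observation carries equal weight; ``season="yearly"`` pools all
    seasons. Any hour without observations is an error naming the hour.
    """
    sub = cleaned if season == "yearly" else cleaned[cleaned["season"] == season]
    grouped = sub.groupby("hour")[value_col]
    means = grouped.mean().reindex(range(24))
    counts = grouped.size().reindex(range(24), fill_value=0)
    if means.isna().any():
        missing = int(means.index[means.isna()][0])
        raise ValueError(f"no observations for hour {missing} in {season!r}")
    return DiurnalProfile(season=season, hourly_mean=means.to_numpy(),
                          hourly_count=counts.to_numpy())


@dataclass
class AdjustmentFactors:
    """24 positive unitless hourly factors averaging to exactly 1."""

    season: str
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, float)
        if self.factors.shape != (24,):
            raise ValueError("need exactly 24 factors")
        if (self.factors <= 0).any():
            raise ValueError("factors must be strictly positive")
        if abs(self.factors.mean() - 1.0) > 1e-12:
            raise ValueError("factors must average to 1")

    def __getitem__(self, hour: int) -> float:
        return float(self.factors[hour])


def adjustment_factors(profile: DiurnalProfile) -> AdjustmentFactors:
    """Hourly factors: each hourly mean divided by the daily mean.

    The daily mean is the unweighted mean of the 24 hourly means, so the
    factors average to 1 by construction (renormalized once to absorb
    floating-point residue).
    """
    daily = profile.daily_mean
    if daily <= 0:
        raise ValueError("daily mean concentration must be positive")
    f = profile.hourly_mean / daily
    f = f / f.mean()  # exact unit mean
    return AdjustmentFactors(season=profile.season, factors=f)


def hourly_map(base: GridRaster, factors: AdjustmentFactors,
               hour: int) -> GridRaster:
    """Scale a seasonal/yearly base map by the hour's adjustment factor.

    Spatially uniform multiplication; nodata cells are preserved.
    """
    if not 0 <= hour < 24:
        raise ValueError("hour must be in 0..23")
    f = factors[hour]
    vals = np.where(base.mask(), base.values * f, base.nodata)
    return base.with_values(vals, name=f"{base.name}_h{hour:02d}")


def factors_frame(all_factors: list[AdjustmentFactors]) -> pd.DataFrame:
    """Long CSV layout: season, hour, factor."""
    rows = [
        {"season": fa.season, "hour": h, "factor": fa.factors[h]}
        for fa in all_factors for h in range(24)
    ]
    return pd.DataFrame(rows)
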