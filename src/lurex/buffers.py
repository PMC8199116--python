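"""Distance-decay buffer search and regression feature tables.

Land-use covariates influence PM2.5 at covariate-specific spatial scales.
For each covariate the package scans a ladder of buffer radii, computes the
circular focal mean at every radius, extracts it at the monitoring sites and
keeps the radius whose buffered covariate correlates most strongly (largest
|Pearson r|) with the observed PM2.5 — the "distance-decay" buffer search.
The covariates at their optimal radii form the regression design matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .raster import GridRaster, extract_at_points, focal_mean

logger = logging.getLogger(__name__)

#: Radii printed in published Beijing LUR prediction functions; the default
#: ladder always includes them.
PUBLISHED_RADII_M = (60, 990, 1500, 1890, 2190, 2370, 2400, 3840, 4020, 4620, 5010)


@dataclass(frozen=True)
class BufferLadder:
    """Strictly increasing candidate buffer radii in meters."""

    radii_m: tuple[float, ...]

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii_m)
        if not radii:
            raise ValueError("buffer ladder must be non-empty")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("buffer radii must be strictly increasing")
        object.__setattr__(self, "radii_m", radii)

    def __iter__(self):
        return iter(self.radii_m)

    def __len__(self) -> int:
        return len(self.radii_m)


def default_ladder(max_radius_m: float = 5010.0, step_m: float = 30.0,
                   exhaustive: bool = False,
                   min_radius_m: float = 0.0) -> BufferLadder:
    """Default distance-decay ladder.

    Dense at short range where neighborhood effects change fastest, thinned
    at long range: every ``step_m`` up to 10 steps, every ``3*step_m`` up to
    50 steps, every ``10*step_m`` beyond, plus every radius that appears in
    the published prediction functions. ``exhaustive=True`` keeps every
    ``step_m`` multiple instead.
    """
    if exhaustive:
        radii = np.arange(step_m, max_radius_m + step_m / 2, step_m)
    else:
        fine = np.arange(step_m, 10 * step_m + step_m / 2, step_m)
        mid = np.arange(12 * step_m, 50 * step_m + step_m / 2, 3 * step_m)
        coarse = np.arange(60 * step_m, max_radius_m + step_m / 2, 10 * step_m)
        radii = np.concatenate([fine, mid, coarse, np.asarray(PUBLISHED_RADII_M, float)])
    radii = np.unique(radii[(radii <= max_radius_m + 1e-9)
                            & (radii >= min_radius_m - 1e-9)])
    return BufferLadder(tuple(radii))


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN when either side has zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def buffer_scan(covariate: GridRaster, site_x, site_y, response,
                ladder: BufferLadder) -> pd.DataFrame:
    """Correlation between buffered covariate and response at every radius.

    Returns a DataFrame with columns ``radius_m`` and ``r`` (signed Pearson
    correlation; NaN where undefined), one row per ladder radius — the audit
    trail of the buffer search.
    """
    response = np.asarray(response, float)
    ok = np.isfinite(response)
    rows = []
    for radius in ladder:
        buffered = focal_mean(covariate, radius)
        vals = extract_at_points(buffered, site_x, site_y)
        use = ok & np.isfinite(vals)
        r = pearson_r(vals[use], response[use]) if use.sum() >= 3 else float("nan")
        rows.append({"radius_m": radius, "r": r})
    return pd.DataFrame(rows)


def optimal_from_scan(scan: pd.DataFrame, name: str = "") -> tuple[float, float]:
    """Winning (radius, signed r) of a buffer scan: max |r|, ties toward
    the smallest radius; all-undefined correlations are an error."""
    if scan["r"].isna().all():
        raise ValueError(
            f"correlation undefined at every radius for covariate "
            f"{name!r} (zero variance)"
        )
    finite = scan.dropna(subset=["r"])
    # first row attaining the max |r| wins => smallest radius
    best = finite.loc[finite["r"].abs().idxmax()]
    idx = finite["r"].abs() >= abs(best["r"]) - 1e-15
    best = finite[idx].iloc[0]
    return float(best["radius_m"]), float(best["r"])


def optimal_buffer(covariate: GridRaster, site_x, site_y, response,
                   ladder: BufferLadder) -> tuple[float, float]:
    """Radius maximizing |Pearson r| between buffered covariate and response.

    Returns ``(radius_m, r)`` with the signed correlation at the winning
    radius. Ties in |r| break toward the smallest radius; radii where the
    correlation is undefined (zero variance) are skipped, and if it is
    undefined at every radius a ``ValueError`` is raised.
    """
    response = np.asarray(response, float)
    if np.sum(np.isfinite(response)) < 3:
        raise ValueError("need at least 3 sites with finite response")
    scan = buffer_scan(covariate, site_x, site_y, response, ladder)
    return optimal_from_scan(scan, covariate.name)


def build_feature_table(covariates: dict[str, GridRaster],
                        chosen_radii: dict[str, float],
                        sites: pd.DataFrame,
                        response: np.ndarray,
                        response_name: str = "pm25") -> pd.DataFrame:
    """Design matrix of buffered covariates at sites plus the response.

    Parameters
    ----------
    covariates : mapping of covariate name to raw raster
    chosen_radii : mapping of covariate name to its optimal buffer radius (m)
    sites : DataFrame with columns ``site_id``, ``x``, ``y`` (one row/site)
    response : observed mean PM2.5 per site (μg/m³)

    Columns are named ``{covariate}{radius:g}m`` (e.g. ``DTS2400m``). Rows
    containing any nodata/NaN are dropped and logged; fewer than 3 complete
    rows is an error.
    """
    table = pd.DataFrame({"site_id": sites["site_id"].to_numpy()})
    for name, radius in chosen_radii.items():
        if name not in covariates:
            raise KeyError(f"unknown covariate {name!r}")
        buffered = focal_mean(covariates[name], radius)
        table[f"{name}{radius:g}m"] = extract_at_points(
            buffered, sites["x"].to_numpy(), sites["y"].to_numpy()
        )
    table[response_name] = np.asarray(response, float)
    table = table.set_index("site_id")
    complete = table.dropna()
    dropped = len(table) - len(complete)
    if dropped:
        logger.info("dropped %d site rows with nodata covariates", dropped)
    if len(complete) < 3:
        raise ValueError(
            f"only {len(complete)} complete site rows; at least 3 required"
        )
    return complete
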