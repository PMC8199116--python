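"""Hourly population distributions from base-station device counts.

The connected-device total of a cellular network swings several-fold over a
day (devices power off or go idle at night), so raw hourly counts cannot be
compared across hours. :func:`standardize_counts` rescales every hourly
column to a common reference total — the mean of the 24 raw totals — which
leaves each hour's *spatial shares* untouched and therefore leaves every
population-weighted mean unchanged.

Commute accounting compares the standardized population inside each nested
ring road at a daytime hour (default 15:00, people at work) against a
nighttime hour (default 2:00, people at home); the entries are cumulative
within nested rings, so the outside zone's entry is exactly the negative of
the outermost ring's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, box, mapping
from shapely.geometry.base import BaseGeometry

OUTSIDE_LABEL = "outside"


@dataclass
class CountMatrix:
    """Base stations x 24 hourly nonnegative device counts, with coords."""

    station_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    counts: np.ndarray  # (n_stations, 24)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 24:
            raise ValueError("counts must be (n_stations, 24)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not (len(self.station_id) == len(self.x) == len(self.y)
                == self.counts.shape[0]):
            raise ValueError("station metadata length mismatch")

    @property
    def n_stations(self) -> int:
        return self.counts.shape[0]

    def hourly_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long CSV layout: station_id, x, y, hour, count."""
        n, _ = self.counts.shape
        return pd.DataFrame({
            "station_id": np.repeat(self.station_id, 24),
            "x": np.repeat(self.x, 24),
            "y": np.repeat(self.y, 24),
            "hour": np.tile(np.arange(24), n),
            "count": self.counts.ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        wide = df.pivot_table(index=["station_id", "x", "y"], columns="hour",
                              values="count", aggfunc="sum").sort_index(level="station_id")
        meta = wide.index.to_frame(index=False)
        return cls(station_id=meta["station_id"].to_numpy(),
                   x=meta["x"].to_numpy(), y=meta["y"].to_numpy(),
                   counts=wide.to_numpy())


@dataclass
class PopulationWeights:
    """Standardized station weights: every hourly column sums to the same
    reference total (within 1e-9 relative error)."""

    station_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray  # (n_stations, 24)
    reference_total: float

    def column(self, hour: int) -> np.ndarray:
        return self.weights[:, hour]

    def day_average(self) -> np.ndarray:
        """Mean weight per station over the 24 standardized hours."""
        return self.weights.mean(axis=1)


def standardize_counts(counts: CountMatrix) -> PopulationWeights:
    """Rescale each hourly column to the mean of the 24 raw column totals.

    Spatial shares within an hour are unchanged; an hour with zero total is
    an error (it has no spatial information to rescale).
    """
    totals = counts.hourly_totals()
    zero = np.nonzero(totals <= 0)[0]
    if zero.size:
        raise ValueError(f"hour {int(zero[0])} has zero total count")
    ref = float(totals.mean())
    weights = counts.counts * (ref / totals)[None, :]
    return PopulationWeights(station_id=counts.station_id, x=counts.x,
                             y=counts.y, weights=weights,
                             reference_total=ref)


# -- ring zones -------------------------------------------------------------

@dataclass
class RingSet:
    """Nested closed ring polygons (innermost first) plus the implicit
    outside zone; together the zones partition the domain."""

    polygons: list[BaseGeometry]
    labels: list[str]
    domain: BaseGeometry
    outside_label: str = OUTSIDE_LABEL

    def __post_init__(self) -> None:
        if len(self.polygons) != len(self.labels):
            raise ValueError("one label per ring polygon required")
        for inner, outer in zip(self.polygons, self.polygons[1:]):
            if not outer.contains(inner):
                raise ValueError("ring polygons must be strictly nested")

    @property
    def zone_labels(self) -> list[str]:
        return [*self.labels, self.outside_label]

    def zone_of(self, x: float, y: float) -> str:
        """Innermost ring containing the point, else the outside zone."""
        p = Point(x, y)
        if not self.domain.intersects(p):
            raise ValueError(f"point ({x}, {y}) outside the domain")
        for poly, label in zip(self.polygons, self.labels):
            if poly.intersects(p):
                return label
        return self.outside_label

    def zone_polygons(self) -> dict[str, BaseGeometry]:
        """Disjoint zone geometries: innermost disc, annuli, outside."""
        zones: dict[str, BaseGeometry] = {}
        prev = None
        for poly, label in zip(self.polygons, self.labels):
            clipped = poly.intersection(self.domain)
            zones[label] = clipped if prev is None else clipped.difference(prev)
            prev = clipped
        zones[self.outside_label] = self.domain.difference(prev)
        return zones

    def to_geojson(self, path: str | Path) -> Path:
        path = Path(path)
        features = [
            {"type": "Feature", "properties": {"ring": label},
             "geometry": mapping(poly)}
            for poly, label in zip(self.polygons, self.labels)
        ]
        path.write_text(json.dumps(
            {"type": "FeatureCollection", "features": features}))
        return path


def make_ring_set(center: tuple[float, float], radii_m, labels,
                  domain_bounds: tuple[float, float, float, float],
                  quad_segs: int = 64) -> RingSet:
    """Concentric circular rings around ``center`` clipped to the domain."""
    radii = tuple(float(r) for r in radii_m)
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("ring radii must be strictly increasing")
    c = Point(*center)
    polys = [c.buffer(r, quad_segs=quad_segs) for r in radii]
    return RingSet(polygons=polys, labels=list(labels),
                   domain=box(*domain_bounds))


def assign_zones(x, y, rings: RingSet) -> np.ndarray:
    """Zone label per point (vector form of :meth:`RingSet.zone_of`)."""
    x = np.atleast_1d(np.asarray(x, float))
    y = np.atleast_1d(np.asarray(y, float))
    return np.array([rings.zone_of(xi, yi) for xi, yi in zip(x, y)],
                    dtype=object)


# -- commute accounting -----------------------------------------------------

@dataclass
class CommuteTable:
    """Cumulative net daytime population change per nested ring.

    ``entries[label]`` is (population within that ring at the daytime hour
    minus at the nighttime hour) as percent of the total population; the
    outside zone carries the exact negative of the outermost ring's entry.
    """

    entries: dict[str, float]
    day_hour: int = 15
    night_hour: int = 2
    outside_label: str = OUTSIDE_LABEL

    @classmethod
    def from_cumulative(cls, ring_labels, cumulative_percent,
                        **kw) -> "CommuteTable":
        """Build from cumulative ring entries; the outside entry is derived
        as the negative of the outermost ring's entry (conservation)."""
        entries = {lab: float(v) for lab, v in zip(ring_labels, cumulative_percent)}
        outside = kw.pop("outside_label", OUTSIDE_LABEL)
        entries[outside] = -entries[list(ring_labels)[-1]]
        return cls(entries=entries, outside_label=outside, **kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "zone": list(self.entries),
            "net_change_percent": list(self.entries.values()),
        })


def commute_net_change(weights: PopulationWeights, rings: RingSet,
                       day_hour: int = 15, night_hour: int = 2
                       ) -> CommuteTable:
    """Net daytime inflow into each nested ring, percent of total population.

    Compares the standardized population distribution at ``day_hour``
    (work) against ``night_hour`` (home). Entries are cumulative within the
    nested rings; because the standardized totals agree across hours, the
    outside entry equals the negative of the outermost ring's entry.
    """
    if not (0 <= day_hour < 24 and 0 <= night_hour < 24):
        raise ValueError("hours must be in 0..23")
    zones = assign_zones(weights.x, weights.y, rings)
    day = weights.column(day_hour)
    night = weights.column(night_hour)
    total = day.sum()
    entries: dict[str, float] = {}
    inside = np.zeros(len(zones), dtype=bool)
    for label in rings.labels:
        inside |= zones == label
        entries[label] = float((day[inside].sum() - night[inside].sum())
                               / total * 100.0)
    entries[rings.outside_label] = -entries[rings.labels[-1]]
    return CommuteTable(entries=entries, day_hour=day_hour,
                        night_hour=night_hour,
                        outside_label=rings.outside_label)
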