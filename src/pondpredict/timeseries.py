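"""Per-pond observation series and their monthly summaries.

Definitions used throughout:

* "cloud-free" means ``cloud_fraction == 0`` exactly;
* the balanced mean area averages each calendar month's mean of cloud-free
  observations, then averages the months that have data (so unevenly sampled
  months carry equal weight);
* the hydroperiod is the average over calendar months of the fraction of
  cloud-free observations with positive area.

Months that were never observed are skipped, not imputed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, InputError
from .water_detection import PondObservation


@dataclass
class PondSeries:
    """All observations of one pond, sorted by date."""

    pond_id: int
    observations: list[PondObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.observations = sorted(self.observations, key=lambda o: o.date)
        for obs in self.observations:
            if obs.pond_id != self.pond_id:
                raise InputError(
                    f"observation for pond {obs.pond_id} in series of pond {self.pond_id}"
                )
        dates = [o.date for o in self.observations]
        if len(set(dates)) != len(dates):
            raise InputError(f"pond {self.pond_id}: duplicate observation dates")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def span(self) -> tuple[int, int]:
        if not self.observations:
            raise EstimationError("empty series has no span")
        return self.observations[0].date.year, self.observations[-1].date.year

    def cloud_free(self) -> list[PondObservation]:
        return [o for o in self.observations if o.cloud_fraction == 0.0]

    def scaled(self, factor: float) -> "PondSeries":
        """Series with every area multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise InputError("scale factor must be positive")
        return PondSeries(
            self.pond_id,
            [
                PondObservation(o.pond_id, o.date, o.area * factor, o.area_max * factor,
                                o.cloud_fraction)
                for o in self.observations
            ],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pond_id": [o.pond_id for o in self.observations],
                "date": [o.date.isoformat() for o in self.observations],
                "area_m2": [o.area for o in self.observations],
                "area_max_m2": [o.area_max for o in self.observations],
                "cloud_fraction": [o.cloud_fraction for o in self.observations],
            }
        )


def series_from_frame(df: pd.DataFrame) -> dict[int, PondSeries]:
    """Build one PondSeries per pond from an areas table.

    Requires columns pond_id, date, area_m2; optional area_max_m2 and
    cloud_fraction default to a cloud-free record.
    """
    required = {"pond_id", "date", "area_m2"}
    if not required <= set(df.columns):
        raise InputError(f"areas table must have columns {sorted(required)}")
    out: dict[int, PondSeries] = {}
    for pond_id, group in df.groupby("pond_id"):
        obs = []
        for rec in group.itertuples(index=False):
            area = float(rec.area_m2)
            area_max = float(getattr(rec, "area_max_m2", area))
            cf = float(getattr(rec, "cloud_fraction", 0.0))
            date = rec.date
            if not isinstance(date, _dt.date) or isinstance(date, _dt.datetime):
                date = pd.Timestamp(date).date()
            obs.append(PondObservation(int(pond_id), date, area, area_max, cf))
        out[int(pond_id)] = PondSeries(int(pond_id), obs)
    return out


@dataclass(frozen=True)
class MonthlyValue:
    """One (year, month) aggregate: mean of the least-clouded observations."""

    year: int
    month: int
    area: float
    area_max: float
    basis: int
    cloud_fraction: float

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise InputError("month must lie in 1..12")
        if self.basis < 1:
            raise InputError("a monthly value must average at least one observation")


def mean_area(series: PondSeries, exclude_zeros: bool = False) -> float:
    """Monthly-balanced mean area over cloud-free observations.

    With ``exclude_zeros`` only wet (area > 0) observations enter the monthly
    means — the water-presence variant of the reference mean.
    """
    monthly: dict[int, list[float]] = {}
    for obs in series.cloud_free():
        if exclude_zeros and obs.area <= 0:
            continue
        monthly.setdefault(obs.date.month, []).append(obs.area)
    if not monthly:
        raise EstimationError(
            f"pond {series.pond_id}: no qualifying cloud-free observations for the mean"
        )
    return float(np.mean([np.mean(v) for v in monthly.values()]))


def hydroperiod(series: PondSeries) -> float:
    """Average over calendar months of the wet fraction of cloud-free observations."""
    monthly: dict[int, list[bool]] = {}
    for obs in series.cloud_free():
        monthly.setdefault(obs.date.month, []).append(obs.area > 0)
    if not monthly:
        raise EstimationError(f"pond {series.pond_id}: no cloud-free observations")
    return float(np.mean([np.mean(v) for v in monthly.values()]))


def monthly_series(series: PondSeries) -> list[MonthlyValue]:
    """One aggregate per observed (year, month).

    Within a month only the observations tied at the lowest cloud fraction are
    averaged; the rest are discarded.  Months with no observations are absent.
    """
    groups: dict[tuple[int, int], list[PondObservation]] = {}
    for obs in series.observations:
        groups.setdefault((obs.date.year, obs.date.month), []).append(obs)
    out = []
    for (year, month) in sorted(groups):
        obs_list = groups[(year, month)]
        cf_min = min(o.cloud_fraction for o in obs_list)
        best = [o for o in obs_list if o.cloud_fraction == cf_min]
        out.append(
            MonthlyValue(
                year=year,
                month=month,
                area=float(np.mean([o.area for o in best])),
                area_max=float(np.mean([o.area_max for o in best])),
                basis=len(best),
                cloud_fraction=cf_min,
            )
        )
    return out


def normalize(series: PondSeries, mean: float) -> list[tuple[int, float]]:
    """Cloud-free observations as (day_of_year, area/mean) pairs."""
    if mean <= 0:
        raise InputError("normalization mean must be positive")
    return [
        (o.date.timetuple().tm_yday, o.area / mean)
        for o in series.cloud_free()
    ]


def max_area(series: PondSeries) -> float:
    """Maximum cloud-free observed area (reference for the MAX-scaled models)."""
    areas = [o.area for o in series.cloud_free()]
    if not areas:
        raise EstimationError(f"pond {series.pond_id}: no cloud-free observations")
    return float(max(areas))
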