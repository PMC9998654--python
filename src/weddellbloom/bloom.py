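"""Bloom occurrence detection and phenology on box-mean chlorophyll series.

A bloom is "present" at a time step when the box-mean chlorophyll-a
exceeds a threshold fitted on the full record: the long-record mean plus
``n_sd`` sample standard deviations (occurrence criterion) or the
long-term median (phenology criterion used for onset/end/duration).
Time series are :class:`pandas.Series` with a ``DatetimeIndex``; gaps
(cloud/ice) are ``NaN`` and never qualify as occurrences.

Austral seasons run Jul 1 - Jun 30 and are labelled by the calendar
year of their July, so a January bloom belongs to the season that
started the previous July.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .grids import RegionBox, validate_field
from .synthetic import austral_season


class EmptyDataError(ValueError):
    """A statistic was requested on an all-missing series."""


@dataclass(frozen=True)
class BloomCriterion:
    """Fitted presence threshold for box-mean chlorophyll (mg m-3)."""

    method: str  # "mean_plus_sd" or "long_term_median"
    threshold: float
    n_sd: float = 1.0


@dataclass(frozen=True)
class BloomEvent:
    """One seasonal bloom: first to last threshold exceedance."""

    season: int  # austral-season label (calendar year of its July)
    onset: pd.Timestamp
    end: pd.Timestamp
    peak_time: pd.Timestamp
    peak_value: float

    @property
    def duration_days(self) -> int:
        return (self.end - self.onset).days


@dataclass
class OccurrenceStats:
    """Occurrence counts by austral season and calendar month."""

    n_years_with_bloom: int
    n_years_total: int
    monthly_distribution: dict[int, float] = field(default_factory=dict)

    @property
    def fraction_of_years(self) -> float:
        return self.n_years_with_bloom / self.n_years_total


def compute_box_mean_series(field: xr.DataArray, box: RegionBox) -> pd.Series:
    """Unweighted mean over non-missing cells inside the box, per time.

    Time steps where every cell in the box is missing come out as NaN.
    """
    validate_field(field)
    sub = box.select(field)
    series = sub.mean(dim=("lat", "lon"), skipna=True).to_series()
    series.name = field.name
    return series


def fit_bloom_criterion(series: pd.Series, method: str = "mean_plus_sd",
                        n_sd: float = 1.0) -> BloomCriterion:
    """Fit the presence threshold on the full record.

    ``mean_plus_sd``: mean + n_sd * sample SD (ddof=1) of all
    non-missing values — the long-record occurrence criterion.
    ``long_term_median``: the record median — the phenology threshold.
    """
    values = series.dropna()
    if values.size < 2:
        raise EmptyDataError("need >=2 non-missing values to fit a criterion")
    if method == "mean_plus_sd":
        threshold = float(values.mean() + n_sd * values.std(ddof=1))
    elif method == "long_term_median":
        threshold = float(values.median())
    else:
        raise ValueError(f"unknown criterion method {method!r}")
    return BloomCriterion(method=method, threshold=threshold, n_sd=n_sd)


def detect_occurrences(series: pd.Series, criterion: BloomCriterion) -> pd.DatetimeIndex:
    """Timestamps whose value strictly exceeds the threshold.

    Missing entries never qualify; ties on the threshold are excluded.
    """
    exceed = series[series > criterion.threshold]
    return pd.DatetimeIndex(exceed.index)


def occurrence_stats(occurrences: pd.DatetimeIndex,
                     record_span: tuple[pd.Timestamp, pd.Timestamp]) -> OccurrenceStats:
    """Season counts and calendar-month distribution of occurrences.

    A season counts as a bloom year iff it holds at least one
    occurrence; ``monthly_distribution`` gives the percentage of
    occurrence timestamps falling in each calendar month (sums to 100
    when any occurrences exist).  Months are attributed from each 8-day
    bin's start date.
    """
    start, end = pd.Timestamp(record_span[0]), pd.Timestamp(record_span[1])
    if end < start:
        raise EmptyDataError("empty record span")
    n_total = austral_season(end) - austral_season(start) + 1
    seasons = {austral_season(t) for t in occurrences}
    months = pd.Series([t.month for t in occurrences], dtype=int)
    dist = {}
    if len(months):
        counts = months.value_counts()
        dist = {int(m): float(100.0 * c / len(months)) for m, c in counts.items()}
    return OccurrenceStats(n_years_with_bloom=len(seasons),
                           n_years_total=n_total,
                           monthly_distribution=dist)


def bloom_phenology(series: pd.Series, criterion: BloomCriterion) -> list[BloomEvent]:
    """Seasonal onset/end/duration/peak from threshold exceedance.

    For each austral season, onset is the first non-missing time with
    value above the threshold and end the last such time; interior gaps
    or dips do not split the event (the record between first and last
    exceedance is one bloom, mirroring a single seasonal bloom bounded
    by cloud/ice gaps).  Seasons with no exceedance yield no event.
    """
    exceed = series[series > criterion.threshold]
    events = []
    for season, chunk in exceed.groupby([austral_season(t) for t in exceed.index]):
        onset, end = chunk.index[0], chunk.index[-1]
        within = series.loc[onset:end].dropna()
        peak_time = within.idxmax()
        events.append(BloomEvent(season=int(season), onset=onset, end=end,
                                 peak_time=peak_time,
                                 peak_value=float(within.max())))
    return sorted(events, key=lambda e: e.onset)
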