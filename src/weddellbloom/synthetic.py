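"""Synthetic satellite grids and vertical profiles with known ground truth.

The generators emulate the statistical structure of the archives the
analysis is designed for — multi-year gridded chlorophyll-a, zonal wind
and sea-ice concentration with a seasonal cycle plus injected anomaly
events, and glider/float-style vertical profiles with a known mixed
layer, a Gaussian bloom layer, instrument dark offset and optical
spikes.  Every injection is recorded in a :class:`SyntheticTruth`
sidecar so that downstream operations can be tested by parameter
recovery rather than against external downloads.

Seasonality is a calendar-bin-indexed sinusoid, spatially uniform by
default: chlorophyll peaks in austral summer (January), zonal wind in
austral autumn (May), sea ice in late winter (September).  Events are
additive box anomalies, so with zero noise the de-seasoned anomaly of an
injected month is known in closed form: an amplitude ``A`` injected in
one calendar bin of one year out of ``N`` leaves an anomaly of
``A * (1 - k/N)`` in event years and ``-A * k/N`` in the other years,
where ``k`` is the number of event years sharing the bin (the
climatology absorbs ``A * k / N``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import erf

from .grids import BLOOM_CORE_BOX, RegionBox

VARIABLES = ("chl", "u_wind", "sea_ice")

#: Calendar month of each variable's seasonal peak (Southern Hemisphere).
SEASONAL_PEAK_MONTH = {"chl": 1, "u_wind": 5, "sea_ice": 9}

UNITS = {"chl": "mg m-3", "u_wind": "m s-1", "sea_ice": "1"}

EIGHT_DAY_BINS_PER_YEAR = 46


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class GridEvent:
    """Additive box anomaly in given months of one calendar year."""

    year: int
    months: tuple[int, ...]
    box: RegionBox
    amplitude: float
    #: For forcing events: months by which this event leads the
    #: chlorophyll response (0 = synchronous).  Recorded in the truth.
    lag_months: int = 0

    def __post_init__(self) -> None:
        if self.lag_months < 0:
            raise ConfigurationError("lag_months must be >= 0")
        if not all(1 <= m <= 12 for m in self.months):
            raise ConfigurationError(f"months must be in 1..12, got {self.months}")


@dataclass
class GridSimConfig:
    """Configuration for the gridded chl / wind / sea-ice simulator."""

    n_years: int = 10
    cadence: str = "monthly"  # "monthly" or "8day"
    start_year: int = 2000
    lat_min: float = -70.0
    lat_max: float = -64.0
    lat_step: float = 0.5
    lon_min: float = 0.0
    lon_max: float = 12.0
    lon_step: float = 1.0
    climatology_mean: dict[str, float] = field(
        default_factory=lambda: {"chl": 0.5, "u_wind": -4.0, "sea_ice": 0.5})
    climatology_amplitude: dict[str, float] = field(
        default_factory=lambda: {"chl": 0.3, "u_wind": 2.0, "sea_ice": 0.4})
    bloom_events: list[GridEvent] = field(default_factory=list)
    wind_anomaly_events: list[GridEvent] = field(default_factory=list)
    ice_anomaly_events: list[GridEvent] = field(default_factory=list)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"chl": 0.0, "u_wind": 0.0, "sea_ice": 0.0})
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ConfigurationError("n_years must be >= 2 (climatology needs >=2 samples/bin)")
        if self.cadence not in ("monthly", "8day"):
            raise ConfigurationError(f"unknown cadence {self.cadence!r}")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ConfigurationError("missing_fraction must be in [0, 1]")
        if self.lat_step <= 0 or self.lon_step <= 0:
            raise ConfigurationError("grid steps must be positive")
        if self.lat_min >= self.lat_max or self.lon_min >= self.lon_max:
            raise ConfigurationError("invalid grid extent")


@dataclass
class SyntheticTruth:
    """Ground truth of all injections made by a generator call."""

    # gridded-simulator truths
    bloom_months: list[pd.Timestamp] = field(default_factory=list)
    bloom_seasons: list[int] = field(default_factory=list)  # austral-season labels
    wind_chl_lag_months: int | None = None
    coupled_box: RegionBox | None = None
    # profile-simulator truths
    mld_m: float | None = None
    poc_inventory_0_100_gC_m2: float | None = None
    spike_depths_m: list[float] = field(default_factory=list)
    dark_offset: float | None = None

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["bloom_months"] = [str(t.date()) for t in self.bloom_months]
        Path(path).write_text(json.dumps(d, indent=2, default=str))


def austral_season(ts: pd.Timestamp) -> int:
    """Label of the austral season (Jul 1 - Jun 30) containing ``ts``.

    The label is the calendar year of the season's July, so January 2019
    belongs to season 2018.
    """
    return ts.year if ts.month >= 7 else ts.year - 1


def _time_axis(config: GridSimConfig) -> pd.DatetimeIndex:
    if config.cadence == "monthly":
        return pd.date_range(f"{config.start_year}-01-01",
                             periods=config.n_years * 12, freq="MS")
    # 46 eight-day bins per year, anchored at Jan 1 of each year
    times = []
    for y in range(config.start_year, config.start_year + config.n_years):
        origin = pd.Timestamp(f"{y}-01-01")
        times.extend(origin + pd.Timedelta(days=8) * k
                     for k in range(EIGHT_DAY_BINS_PER_YEAR))
    return pd.DatetimeIndex(times)


def calendar_bin(times: pd.DatetimeIndex, cadence: str) -> np.ndarray:
    """Calendar bin of each timestamp: month 1..12 or 8-day bin 0..45."""
    if cadence == "monthly":
        return times.month.to_numpy()
    return np.minimum((times.dayofyear.to_numpy() - 1) // 8,
                      EIGHT_DAY_BINS_PER_YEAR - 1)


def seasonal_cycle(config: GridSimConfig, var: str,
                   times: pd.DatetimeIndex) -> np.ndarray:
    """Closed-form seasonal climatology value at each time (no noise)."""
    mean = config.climatology_mean[var]
    amp = config.climatology_amplitude[var]
    peak = SEASONAL_PEAK_MONTH[var]
    if config.cadence == "monthly":
        phase = (times.month.to_numpy() - peak) / 12.0
    else:
        bins = calendar_bin(times, "8day")
        peak_bin = (peak - 1) * EIGHT_DAY_BINS_PER_YEAR / 12.0
        phase = (bins - peak_bin) / EIGHT_DAY_BINS_PER_YEAR
    return mean + amp * np.cos(2.0 * np.pi * phase)


def generate_gridded_dataset(
    config: GridSimConfig,
) -> tuple[dict[str, xr.DataArray], SyntheticTruth]:
    """Simulate the chl / zonal-wind / sea-ice field triple.

    Each field is seasonal climatology + injected box events + Gaussian
    noise, with ``missing_fraction`` of cells masked completely at
    random.  Returns the fields keyed by variable name and the truth of
    every injection.
    """
    rng = np.random.default_rng(config.seed)
    times = _time_axis(config)
    lat = np.arange(config.lat_min, config.lat_max + 1e-9, config.lat_step)
    lon = np.arange(config.lon_min, config.lon_max + 1e-9, config.lon_step)
    shape = (times.size, lat.size, lon.size)

    events = {"chl": config.bloom_events,
              "u_wind": config.wind_anomaly_events,
              "sea_ice": config.ice_anomaly_events}
    fields: dict[str, xr.DataArray] = {}
    for var in VARIABLES:
        values = np.broadcast_to(
            seasonal_cycle(config, var, times)[:, None, None], shape).copy()
        da = xr.DataArray(values, dims=("time", "lat", "lon"),
                          coords={"time": times, "lat": lat, "lon": lon},
                          name=var, attrs={"units": UNITS[var]})
        for ev in events[var]:
            in_time = (times.year == ev.year) & np.isin(times.month, ev.months)
            if not in_time.any():
                raise ConfigurationError(
                    f"event {ev} falls outside the simulated record")
            box = ev.box.mask(da).values
            da.values[np.ix_(np.flatnonzero(in_time))] += ev.amplitude * box
        sd = config.noise_sd.get(var, 0.0)
        if sd > 0:
            da.values[:] += rng.normal(0.0, sd, size=shape)
        if config.missing_fraction > 0:
            n_missing = int(round(config.missing_fraction * da.size))
            flat = rng.choice(da.size, size=n_missing, replace=False)
            da.values.ravel()[flat] = np.nan
        fields[var] = da

    bloom_months = sorted(
        pd.Timestamp(year=ev.year, month=m, day=1)
        for ev in config.bloom_events for m in ev.months)
    lags = {ev.lag_months for ev in config.wind_anomaly_events}
    truth = SyntheticTruth(
        bloom_months=bloom_months,
        bloom_seasons=sorted({austral_season(t) for t in bloom_months}),
        wind_chl_lag_months=lags.pop() if len(lags) == 1 else None,
        coupled_box=config.bloom_events[0].box if config.bloom_events else None,
    )
    return fields, truth


def recurring_bloom_config(seed: int = 0) -> GridSimConfig:
    """The study-condition grid: a recurrent late-summer bloom forced by
    easterly wind anomalies one month earlier.

    Ten years of monthly fields; chlorophyll bloom events (amplitude
    1.5 mg m-3, Jan-Feb) injected in 4 of the 10 austral seasons inside
    the bloom core box; each bloom season carries a negative zonal-wind
    anomaly (-3 m s-1) in the preceding Dec-Jan, i.e. winds lead the
    bloom by one month; a matching negative sea-ice anomaly accompanies
    the wind events.  Moderate observational noise on every field.
    """
    box = BLOOM_CORE_BOX
    base = 2000
    bloom_years = (2, 4, 6, 9)  # austral seasons base+1, +3, +5, +8
    bloom_events, wind_events, ice_events = [], [], []
    for dy in bloom_years:
        y = base + dy
        bloom_events.append(GridEvent(y, (1, 2), box, 1.5))
        # wind (and ice) anomalies lead the Jan-Feb bloom by 1 month
        wind_events.append(GridEvent(y - 1, (12,), box, -3.0, lag_months=1))
        wind_events.append(GridEvent(y, (1,), box, -3.0, lag_months=1))
        ice_events.append(GridEvent(y - 1, (12,), box, -0.15, lag_months=1))
        ice_events.append(GridEvent(y, (1,), box, -0.15, lag_months=1))
    return GridSimConfig(
        n_years=10, cadence="monthly", start_year=base,
        bloom_events=bloom_events, wind_anomaly_events=wind_events,
        ice_anomaly_events=ice_events,
        noise_sd={"chl": 0.05, "u_wind": 0.5, "sea_ice": 0.03},
        missing_fraction=0.02, seed=seed)


# ---------------------------------------------------------------------------
# vertical profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileSimConfig:
    """Configuration for a single synthetic glider/float profile.

    The optical channels are a Gaussian bloom layer (chlorophyll in raw
    fluorescence counts with an instrument dark offset; POC in mg m-3)
    plus optional discrete spikes emulating large sinking particles, and
    Gaussian noise.  Temperature and potential density are two-layer
    step profiles whose step sits exactly at ``true_mld``.
    """

    depth_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 1000.0 + 1e-9, 1.0))
    true_mld: float = 50.0
    surface_temperature: float = 0.5      # deg C
    temperature_step: float = 1.0         # cooling across the MLD, deg C
    surface_sigma: float = 27.4           # kg m-3
    sigma_step: float = 0.1               # densification across the MLD
    bloom_center: float = 40.0            # m
    bloom_width: float = 15.0             # Gaussian sigma, m
    peak_chl_counts: float = 300.0        # raw fluorescence counts
    peak_poc: float = 200.0               # mg m-3
    dark_offset: float = 50.0             # counts added to the chl channel
    spike_depths: tuple[float, ...] = ()
    spike_amplitude: float = 0.0          # added to both optical channels
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        z = np.asarray(self.depth_grid, dtype=float)
        if z.ndim != 1 or z.size < 3 or not np.all(np.diff(z) > 0):
            raise ConfigurationError("depth_grid must be 1-D, strictly increasing, >=3 points")
        self.depth_grid = z
        if not z[0] <= self.true_mld <= z[-1]:
            raise ConfigurationError("true_mld outside depth_grid range")
        if self.bloom_width <= 0:
            raise ConfigurationError("bloom_width must be > 0")
        if self.peak_chl_counts < 0 or self.peak_poc < 0 or self.spike_amplitude < 0:
            raise ConfigurationError("amplitudes must be >= 0")
        for d in self.spike_depths:
            if not z[0] <= d <= z[-1]:
                raise ConfigurationError(f"spike depth {d} outside depth_grid")


def gaussian_layer_integral(peak: float, center: float, width: float,
                            z_top: float, z_bottom: float) -> float:
    """Closed-form integral of ``peak * exp(-(z-center)^2 / (2 width^2))``
    over ``[z_top, z_bottom]`` (same depth units as the inputs)."""
    s = width * np.sqrt(2.0)
    return float(peak * width * np.sqrt(np.pi / 2.0)
                 * (erf((z_bottom - center) / s) - erf((z_top - center) / s)))


def generate_profile(config: ProfileSimConfig):
    """Simulate one profile; returns ``(Profile, SyntheticTruth)``.

    The truth holds the exact MLD, the analytic 0-100 m POC inventory of
    the Gaussian layer (spikes and noise excluded), the spike depths and
    the dark offset.
    """
    from .profiles import Profile  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed)
    z = config.depth_grid
    below = z > config.true_mld
    temp = np.full_like(z, config.surface_temperature)
    temp[below] -= config.temperature_step
    sigma = np.full_like(z, config.surface_sigma)
    sigma[below] += config.sigma_step

    layer = np.exp(-0.5 * ((z - config.bloom_center) / config.bloom_width) ** 2)
    chl = config.dark_offset + config.peak_chl_counts * layer
    poc = config.peak_poc * layer
    for d in config.spike_depths:
        i = int(np.argmin(np.abs(z - d)))
        chl[i] += config.spike_amplitude
        poc[i] += config.spike_amplitude
    if config.noise_sd > 0:
        chl = chl + rng.normal(0.0, config.noise_sd, z.size)
        poc = poc + rng.normal(0.0, config.noise_sd, z.size)

    profile = Profile(
        depth=z, temperature=temp, sigma=sigma, chl=chl, poc=poc,
        units={"chl": "counts", "poc": "mg m-3"})
    truth = SyntheticTruth(
        mld_m=config.true_mld,
        poc_inventory_0_100_gC_m2=gaussian_layer_integral(
            config.peak_poc, config.bloom_center, config.bloom_width, 0.0, 100.0) / 1000.0,
        spike_depths_m=[float(z[np.argmin(np.abs(z - d))]) for d in config.spike_depths],
        dark_offset=config.dark_offset)
    return profile, truth


def random_profile_configs(n: int, seed: int = 0,
                           depth_step: float = 1.0) -> list[ProfileSimConfig]:
    """Draw ``n`` noiseless-tail profile configurations with randomized
    MLD, bloom layer and stratification, for parameter-recovery tests."""
    rng = np.random.default_rng(seed)
    z = np.arange(0.0, 1000.0 + 1e-9, depth_step)
    configs = []
    for k in range(n):
        configs.append(ProfileSimConfig(
            depth_grid=z,
            true_mld=float(rng.uniform(20.0, 150.0)),
            surface_temperature=float(rng.uniform(-1.5, 2.0)),
            temperature_step=float(rng.uniform(0.2, 2.0)),
            surface_sigma=float(rng.uniform(27.0, 27.6)),
            sigma_step=float(rng.uniform(0.05, 0.4)),
            bloom_center=float(rng.uniform(20.0, 60.0)),
            bloom_width=float(rng.uniform(8.0, 25.0)),
            peak_chl_counts=float(rng.uniform(100.0, 500.0)),
            peak_poc=float(rng.uniform(50.0, 1000.0)),
            dark_offset=float(rng.uniform(20.0, 80.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return configs


def write_gridded_netcdf(fields: dict[str, xr.DataArray], path: str | Path) -> None:
    """Write the field triple as one CF-style NetCDF file."""
    ds = xr.Dataset(fields)
    ds.to_netcdf(path, engine="scipy")


def write_profile_csv(profile, path: str | Path) -> None:
    profile.to_csv(path)
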