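"""De-seasoned anomalies, bloom composites and lagged correlation maps.

De-seasoning removes the per-pixel calendar-bin climatology (monthly, or
46 eight-day bins) from a gridded record, isolating interannual
variability.  Composite maps average those anomalies over a selected
time subset (e.g. months when the bloom was present).  Lagged
correlation maps give the per-pixel Pearson r between a response field
(chlorophyll) and a forcing field (zonal wind, sea ice) where positive
lag means the forcing leads the response — the convention in which
"winds lead the bloom by one month" is lag = +1.

Pearson r uses pairwise-complete observations per pixel; pixels/lags
with fewer than ``min_pairs`` valid pairs (default 3) or zero variance
are undefined (NaN).  No detrending is applied beyond de-seasoning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .grids import GeometryError, validate_field
from .synthetic import EIGHT_DAY_BINS_PER_YEAR, calendar_bin


def _infer_cadence(times: pd.DatetimeIndex) -> str:
    step = np.median(np.diff(times.values).astype("timedelta64[D]").astype(int))
    return "8day" if step <= 9 else "monthly"


def compute_climatology(field: xr.DataArray, cadence: str | None = None) -> xr.Dataset:
    """Per-pixel calendar-bin mean and contributing-sample count.

    Returns a Dataset with variables ``mean`` and ``count`` over
    dimension ``bin`` (month 1..12 for monthly data, 0..45 for 8-day
    data).  Bins with zero valid samples at a pixel are NaN there and
    propagate as missing through :func:`deseason`.
    """
    validate_field(field)
    times = pd.DatetimeIndex(field.time.values)
    cadence = cadence or _infer_cadence(times)
    bins = calendar_bin(times, cadence)
    binned = field.assign_coords(bin=("time", bins)).groupby("bin")
    mean = binned.mean(skipna=True)
    count = binned.count()
    clim = xr.Dataset({"mean": mean, "count": count})
    clim.attrs["cadence"] = cadence
    return clim


def deseason(field: xr.DataArray, climatology: xr.Dataset) -> xr.DataArray:
    """Anomaly = value minus the climatology of its calendar bin."""
    validate_field(field)
    if not (np.array_equal(field.lat, climatology["mean"].lat)
            and np.array_equal(field.lon, climatology["mean"].lon)):
        raise GeometryError("field and climatology are on different grids")
    times = pd.DatetimeIndex(field.time.values)
    bins = calendar_bin(times, climatology.attrs["cadence"])
    anom = field - climatology["mean"].sel(bin=xr.DataArray(bins, dims="time"))
    anom = anom.drop_vars("bin")
    anom.name = f"{field.name}_anomaly" if field.name else "anomaly"
    anom.attrs = dict(field.attrs)
    return anom


@dataclass
class CompositeMap:
    """Mean anomaly map over a selected time subset."""

    map: xr.DataArray
    n_times: int
    n_total: int
    label: str = ""

    @property
    def fraction_of_record(self) -> float:
        return self.n_times / self.n_total


def composite_map(anomalies: xr.DataArray, selected_times,
                  label: str = "") -> CompositeMap:
    """Per-pixel mean anomaly over ``selected_times`` (subset of the record)."""
    times = pd.DatetimeIndex(anomalies.time.values)
    selected = pd.DatetimeIndex(selected_times)
    if len(selected) == 0:
        raise ValueError("empty composite selection")
    missing = selected.difference(times)
    if len(missing):
        raise ValueError(f"selected times not in record: {list(missing[:3])}...")
    comp = anomalies.sel(time=selected).mean(dim="time", skipna=True)
    return CompositeMap(map=comp, n_times=len(selected), n_total=len(times),
                        label=label)


@dataclass
class LagCorrelationResult:
    """Per-pixel Pearson r maps across lags.

    ``r`` and ``n`` have dims (lag, lat, lon); ``best_lag`` holds, per
    pixel, the lag of maximum absolute r.  ``extreme_r`` is the single
    largest-|r| value over the whole domain with its lag — the analogue
    of reporting one boxed maximum correlation.
    """

    r: xr.DataArray
    n: xr.DataArray
    p: xr.DataArray
    lags: list[int]
    best_lag: xr.DataArray
    extreme_r: float
    extreme_lag: int


def lagged_correlation_map(response: xr.DataArray, forcing: xr.DataArray,
                           lags=(0, 1, 2), min_pairs: int = 3,
                           fdr: bool = False) -> LagCorrelationResult:
    """Pearson r between response(t) and forcing(t - lag), per pixel.

    Positive lag means the forcing leads the response by that many time
    steps (months for monthly data).  Pairs are formed over times where
    both fields are valid.  Two-sided p-values come from the t
    distribution with the pairwise n; with ``fdr=True`` they are
    Benjamini-Hochberg adjusted across the map (per lag).
    """
    validate_field(response)
    validate_field(forcing)
    if not np.array_equal(response.time, forcing.time):
        raise GeometryError("response and forcing must share the time axis")
    lags = [int(l) for l in lags]
    if any(l < 0 for l in lags):
        raise ValueError("lags must be >= 0 (forcing leads response)")

    a = response.transpose("time", "lat", "lon").values
    b = forcing.transpose("time", "lat", "lon").values
    nt = a.shape[0]
    r_maps, n_maps, p_maps = [], [], []
    for lag in lags:
        if lag >= nt - 1:
            raise ValueError(f"lag {lag} too large for record length {nt}")
        x = a[lag:]           # response at t
        y = b[: nt - lag]     # forcing at t - lag
        valid = np.isfinite(x) & np.isfinite(y)
        n = valid.sum(axis=0)
        xm = np.where(valid, x, 0.0)
        ym = np.where(valid, y, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sx = xm.sum(0)
            sy = ym.sum(0)
            sxx = (xm * xm).sum(0)
            syy = (ym * ym).sum(0)
            sxy = (xm * ym).sum(0)
            cov = sxy - sx * sy / n
            vx = sxx - sx * sx / n
            vy = syy - sy * sy / n
            r = cov / np.sqrt(vx * vy)
        r[(n < min_pairs) | (vx <= 0) | (vy <= 0)] = np.nan
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
            p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
        p[~np.isfinite(r)] = np.nan
        if fdr:
            flat = p.ravel()
            ok = np.isfinite(flat)
            if ok.any():
                flat[ok] = stats.false_discovery_control(flat[ok])
            p = flat.reshape(p.shape)
        r_maps.append(r)
        n_maps.append(n)
        p_maps.append(p)

    coords = {"lag": lags, "lat": response.lat, "lon": response.lon}
    dims = ("lag", "lat", "lon")
    r_da = xr.DataArray(np.stack(r_maps), dims=dims, coords=coords, name="pearson_r")
    n_da = xr.DataArray(np.stack(n_maps), dims=dims, coords=coords, name="n_pairs")
    p_da = xr.DataArray(np.stack(p_maps), dims=dims, coords=coords, name="p_value")

    absr = np.abs(r_da.values)
    all_nan = np.all(np.isnan(absr), axis=0)
    idx = np.nanargmax(np.where(np.isnan(absr), -np.inf, absr), axis=0)
    best = np.array(lags)[idx].astype(float)
    best[all_nan] = np.nan
    best_da = xr.DataArray(best, dims=("lat", "lon"),
                           coords={"lat": response.lat, "lon": response.lon},
                           name="best_lag")
    if np.all(np.isnan(absr)):
        extreme_r, extreme_lag = np.nan, lags[0]
    else:
        k = np.unravel_index(np.nanargmax(np.where(np.isnan(absr), -np.inf, absr)),
                             absr.shape)
        extreme_r = float(r_da.values[k])
        extreme_lag = lags[k[0]]
    return LagCorrelationResult(r=r_da, n=n_da, p=p_da, lags=lags,
                                best_lag=best_da, extreme_r=extreme_r,
                                extreme_lag=extreme_lag)
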