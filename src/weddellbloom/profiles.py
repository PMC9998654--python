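"""Vertical profile processing: optics, mixed layer depth, inventories.

Implements the glider/float treatment chain: in-situ dark-count
correction (deep-percentile subtraction), optical de-spiking (3-point
rolling-mean baseline), empirical linear calibration against bottle
casts, two mixed-layer-depth criteria (temperature difference from the
surface, potential-density difference from 10 m), trapezoidal column
inventories, the mixed-layer POC:Chl ratio, and the screening of
high-POC float profiles with a subduction exclusion.

Depths are meters, positive down, strictly increasing.  The surface
reference for the temperature criterion is the shallowest non-missing
sample, because gliders rarely sample 0 m.  Criterion crossings are
linearly interpolated between the bracketing samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

CSV_COLUMNS = ("depth_m", "temp_C", "sigma_kg_m3", "chl_counts", "poc_mg_m3")


class InsufficientDepthError(ValueError):
    """Not enough samples in the requested depth range."""


class CalibrationError(ValueError):
    """Bottle calibration could not be fitted."""


@dataclass
class Profile:
    """Depth-ordered vertical samples of one glider/float dive.

    Channels (``temperature``, ``sigma``, ``chl``, ``poc``) are numpy
    arrays aligned with ``depth``; NaN marks missing samples.  ``units``
    tracks the physical unit of each optical channel ("counts" before
    calibration, "mg m-3" after).
    """

    depth: np.ndarray
    temperature: np.ndarray | None = None
    sigma: np.ndarray | None = None
    chl: np.ndarray | None = None
    poc: np.ndarray | None = None
    units: dict[str, str] = field(default_factory=dict)
    timestamp: pd.Timestamp | None = None
    lat: float | None = None
    lon: float | None = None
    profile_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size < 2:
            raise ValueError("depth must be 1-D with >=2 samples")
        if not np.all(np.diff(self.depth) > 0):
            raise ValueError("depths must be strictly increasing")
        for name in ("temperature", "sigma", "chl", "poc"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.depth.shape:
                    raise ValueError(f"channel {name} length != depth length")
                setattr(self, name, v)

    def channel(self, name: str) -> np.ndarray:
        v = getattr(self, name, None)
        if v is None:
            raise ValueError(f"profile has no channel {name!r}")
        return v

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "depth_m": self.depth,
            "temp_C": self.temperature,
            "sigma_kg_m3": self.sigma,
            "chl_counts": self.chl,
            "poc_mg_m3": self.poc,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "Profile":
        df = pd.read_csv(path)
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"profile CSV missing columns {sorted(missing)}")
        return cls(depth=df["depth_m"].to_numpy(),
                   temperature=df["temp_C"].to_numpy(),
                   sigma=df["sigma_kg_m3"].to_numpy(),
                   chl=df["chl_counts"].to_numpy(),
                   poc=df["poc_mg_m3"].to_numpy(),
                   units={"chl": "counts", "poc": "mg m-3"}, **kwargs)


@dataclass(frozen=True)
class BottleCast:
    """Discrete-depth calibration samples from a CTD-rosette cast."""

    depths: np.ndarray
    chl: np.ndarray | None = None  # mg m-3
    poc: np.ndarray | None = None  # mg m-3


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of bottle concentration on sensor signal."""

    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class MLDResult:
    """Mixed-layer depth from one criterion; NaN depth if undetermined."""

    depth_m: float
    method: str
    params: dict

    @property
    def determined(self) -> bool:
        return np.isfinite(self.depth_m)


@dataclass(frozen=True)
class ColumnInventory:
    """Depth-integrated concentration, g m-2 (from mg m-3 x m / 1000)."""

    variable: str
    z_top: float
    z_bottom: float
    value_g_m2: float


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------

def dark_value(profile: Profile, channel: str,
               depth_range: tuple[float, float] = (400.0, 600.0),
               percentile: float = 95.0) -> float:
    """In-situ dark signal: the given percentile of the channel inside
    the deep depth window (default 95th percentile of 400-600 m)."""
    z = profile.depth
    v = profile.channel(channel)
    sel = (z >= depth_range[0]) & (z <= depth_range[1]) & np.isfinite(v)
    if sel.sum() < 3:
        raise InsufficientDepthError(
            f"need >=3 samples in {depth_range} m for a dark estimate, got {sel.sum()}")
    return float(np.percentile(v[sel], percentile))


def dark_correct(profile: Profile, channel: str,
                 depth_range: tuple[float, float] = (400.0, 600.0),
                 percentile: float = 95.0) -> Profile:
    """Subtract the deep-percentile dark signal from the channel.

    No clipping: slightly negative corrected values at depth are left in
    place.  The dark value used is recorded in ``profile.meta``.
    """
    dark = dark_value(profile, channel, depth_range, percentile)
    out = replace(profile, **{channel: profile.channel(channel) - dark})
    out.meta = dict(profile.meta, **{f"dark_{channel}": dark})
    return out


def despike(profile: Profile, channel: str,
            window: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Split a channel into rolling-mean baseline and spike residual.

    The baseline is a centered rolling mean (window shrinks at the
    profile edges); spikes = raw - baseline, so baseline + spikes
    reconstructs the raw channel bit-exactly.  Large positive spikes
    mark discrete sinking particles crossing the optical path.
    """
    v = profile.channel(channel)
    if v.size < window:
        raise ValueError(f"need >= {window} samples to despike")
    baseline = (pd.Series(v).rolling(window, center=True, min_periods=1)
                .mean().to_numpy())
    return baseline, v - baseline


def calibrate(profile: Profile, channel: str, bottles: BottleCast,
              match_tolerance: float = 5.0,
              through_origin: bool = False) -> tuple[Profile, CalibrationFit]:
    """Convert a sensor channel to physical units against bottle samples.

    Each bottle depth is matched to the nearest profile sample within
    ``match_tolerance`` meters; bottle concentration is regressed on
    the sensor signal by OLS (optionally through the origin) and the
    fitted line applied to the whole channel.
    """
    bottle_vals = getattr(bottles, channel, None)
    if bottle_vals is None:
        raise CalibrationError(f"bottle cast has no {channel!r} values")
    z = profile.depth
    v = profile.channel(channel)
    sensor, measured = [], []
    for bz, bv in zip(np.asarray(bottles.depths, float), np.asarray(bottle_vals, float)):
        i = int(np.argmin(np.abs(z - bz)))
        if abs(z[i] - bz) <= match_tolerance and np.isfinite(v[i]) and np.isfinite(bv):
            sensor.append(v[i])
            measured.append(bv)
    sensor = np.array(sensor)
    measured = np.array(measured)
    if sensor.size < 2:
        raise CalibrationError(
            f"only {sensor.size} bottle depths matched within {match_tolerance} m")
    if np.ptp(sensor) == 0:
        raise CalibrationError("zero sensor variance across matched depths")
    if through_origin:
        slope = float(np.sum(sensor * measured) / np.sum(sensor**2))
        intercept = 0.0
        resid = measured - slope * sensor
        tot = np.sum(measured**2)
        r2 = float(1.0 - np.sum(resid**2) / tot) if tot > 0 else np.nan
    else:
        fit = stats.linregress(sensor, measured)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    out = replace(profile, **{channel: slope * v + intercept})
    out.units = dict(profile.units, **{channel: "mg m-3"})
    out.meta = dict(profile.meta, **{f"calibration_{channel}": (slope, intercept)})
    return out, CalibrationFit(slope=slope, intercept=intercept,
                               r_squared=r2, n=int(sensor.size))


# ---------------------------------------------------------------------------
# mixed layer depth
# ---------------------------------------------------------------------------

def _first_crossing(z: np.ndarray, excess: np.ndarray) -> float:
    """Shallowest depth where ``excess`` first becomes > 0, linearly
    interpolated between the bracketing samples; NaN if never."""
    above = excess > 0
    if not above.any():
        return np.nan
    i = int(np.argmax(above))
    if i == 0:
        return float(z[0])
    z0, z1 = z[i - 1], z[i]
    e0, e1 = excess[i - 1], excess[i]
    if not (np.isfinite(e0) and np.isfinite(e1)) or e1 == e0:
        return float(z1)
    return float(z0 + (0.0 - e0) / (e1 - e0) * (z1 - z0))


def mld_temperature(profile: Profile, delta: float = 0.04) -> MLDResult:
    """MLD as the depth where |T - T_surface| first exceeds ``delta``.

    The absolute difference is used so that near-freezing temperature
    inversions, common in Antarctic summer, are handled symmetrically.
    Surface reference is the shallowest non-missing sample.
    """
    t = profile.channel("temperature")
    ok = np.isfinite(t)
    if not ok.any():
        raise ValueError("all-missing temperature channel")
    z = profile.depth[ok]
    t = t[ok]
    depth = _first_crossing(z, np.abs(t - t[0]) - delta)
    return MLDResult(depth_m=depth, method="temp_threshold",
                     params={"delta_C": delta})


def mld_density(profile: Profile, delta: float = 0.03,
                ref_depth: float = 10.0) -> MLDResult:
    """MLD as the depth below ``ref_depth`` where potential density
    first exceeds its reference value by ``delta`` (kg m-3).

    The standard fixed-threshold criterion referenced to 10 m; the
    reference density is linearly interpolated onto ``ref_depth``.
    """
    s = profile.channel("sigma")
    ok = np.isfinite(s)
    z = profile.depth[ok]
    s = s[ok]
    if z.size < 2 or z[-1] < ref_depth:
        raise InsufficientDepthError(
            f"profile does not reach the {ref_depth} m reference depth")
    sigma_ref = float(np.interp(ref_depth, z, s))
    below = z >= ref_depth
    depth = _first_crossing(z[below], s[below] - sigma_ref - delta)
    return MLDResult(depth_m=depth, method="sigma_threshold",
                     params={"delta_kg_m3": delta, "ref_depth_m": ref_depth})


# ---------------------------------------------------------------------------
# inventories and ratios
# ---------------------------------------------------------------------------

def _resample_to_range(z: np.ndarray, v: np.ndarray,
                       z_top: float, z_bottom: float) -> tuple[np.ndarray, np.ndarray]:
    """Samples restricted to [z_top, z_bottom] with the boundaries
    inserted: the shallowest value is extended to z_top if the profile
    starts deeper; z_bottom is linearly interpolated if sampled past."""
    ok = np.isfinite(v)
    z, v = z[ok], v[ok]
    if z.size < 2 or z[0] >= z_bottom or z[-1] <= z_top:
        raise InsufficientDepthError(
            f"need >=2 samples intersecting [{z_top}, {z_bottom}] m")
    inside = (z >= z_top) & (z <= z_bottom)
    zi, vi = list(z[inside]), list(v[inside])
    if not zi or zi[0] > z_top:
        # nearest-value extension toward the surface, interpolation if bracketed
        v_top = float(np.interp(z_top, z, v)) if z[0] < z_top else float(v[0])
        zi.insert(0, z_top)
        vi.insert(0, v_top)
    if zi[-1] < z_bottom and z[-1] > z_bottom:
        zi.append(z_bottom)
        vi.append(float(np.interp(z_bottom, z, v)))
    return np.array(zi), np.array(vi)


def integrate_column(profile: Profile, channel: str,
                     z_top: float = 0.0, z_bottom: float = 100.0) -> ColumnInventory:
    """Trapezoidal column inventory of a concentration channel, g m-2.

    The channel must be in mg m-3 (calibrated); mg m-2 are converted to
    g m-2 by dividing by 1000.
    """
    if z_top >= z_bottom:
        raise ValueError("z_top must be < z_bottom")
    z, v = _resample_to_range(profile.depth, profile.channel(channel),
                              z_top, z_bottom)
    value = float(np.trapezoid(v, z)) / 1000.0
    return ColumnInventory(variable=channel, z_top=z_top, z_bottom=z_bottom,
                           value_g_m2=value)


def ml_poc_chl_ratio(profile: Profile, mld: MLDResult) -> float:
    """Mixed-layer POC:Chl ratio (g:g) from depth-weighted means.

    Both channels must be calibrated to mg m-3; a ratio above ~200
    indicates substantial detrital/heterotrophic carbon or a senescent
    bloom.
    """
    if not mld.determined:
        raise ValueError("undetermined MLD: cannot form a mixed-layer ratio")
    for ch in ("poc", "chl"):
        if profile.units.get(ch, "mg m-3") != "mg m-3":
            raise ValueError(f"channel {ch!r} is not calibrated to mg m-3")
    top = float(profile.depth[0])
    poc = integrate_column(profile, "poc", top, mld.depth_m).value_g_m2
    chl = integrate_column(profile, "chl", top, mld.depth_m).value_g_m2
    if chl == 0:
        raise ZeroDivisionError("zero mixed-layer chlorophyll mean")
    return poc / chl


# ---------------------------------------------------------------------------
# float-profile screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Outcome of the high-POC profile screen.

    ``percentage`` is 100 * n_selected / n_total rounded to 2 decimals —
    the share of the archive retained by the screen.
    """

    n_selected: int
    n_total: int
    selected_ids: list = field(default_factory=list)
    below_ml_fractions: dict = field(default_factory=dict)
    undetermined_mld_ids: list = field(default_factory=list)

    @property
    def percentage(self) -> float:
        if self.n_total == 0:
            raise ValueError("empty profile set")
        return round(100.0 * self.n_selected / self.n_total, 2)

    @classmethod
    def from_counts(cls, n_selected: int, n_total: int) -> "ScreenResult":
        return cls(n_selected=n_selected, n_total=n_total)


def screen_high_poc_profiles(profiles: list[Profile],
                             threshold_g_m2: float = 15.0,
                             below_ml_fraction: float = 0.9,
                             z_bottom: float = 100.0) -> ScreenResult:
    """Select float profiles with anomalously high upper-ocean POC.

    A profile is selected when its 0-100 m POC inventory strictly
    exceeds ``threshold_g_m2`` AND at most ``below_ml_fraction`` of that
    inventory lies below the (density-criterion) mixed layer — the
    second condition excludes eddy-subduction events that pump organic
    matter downward in one short-lived process rather than reflecting
    local accumulation.  Profiles whose MLD is undetermined skip the
    subduction test but are retained (and flagged).
    """
    selected, fractions, undetermined = [], {}, []
    for k, p in enumerate(profiles):
        pid = p.profile_id if p.profile_id is not None else k
        top = float(p.depth[0])
        inv = integrate_column(p, "poc", top, z_bottom).value_g_m2
        if not inv > threshold_g_m2:
            continue
        try:
            mld = mld_density(p)
        except InsufficientDepthError:
            mld = MLDResult(np.nan, "sigma_threshold", {})
        if mld.determined and mld.depth_m < z_bottom:
            below = integrate_column(p, "poc", mld.depth_m, z_bottom).value_g_m2
            frac = below / inv if inv > 0 else np.nan
            fractions[pid] = frac
            if frac > below_ml_fraction:
                continue
        elif not mld.determined:
            undetermined.append(pid)
            warnings.warn(f"profile {pid}: undetermined MLD, subduction test skipped")
        else:  # MLD at/below z_bottom: nothing below the ML inside the column
            fractions[pid] = 0.0
        selected.append(pid)
    return ScreenResult(n_selected=len(selected), n_total=len(profiles),
                        selected_ids=selected, below_ml_fractions=fractions,
                        undetermined_mld_ids=undetermined)
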