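# Methods

## Scope and data model

The package analyses multi-year gridded records (chlorophyll-a, zonal
wind, sea-ice concentration) and vertical optical/hydrographic
profiles. Gridded fields are `xarray.DataArray`s with dims
`(time, lat, lon)`, NaN for missing cells and a `units` attribute;
time series are pandas Series on a `DatetimeIndex`; profiles are a
small dataclass of depth-aligned numpy channels with tracked units.
No bespoke containers or parsers are used: NetCDF goes through xarray
(scipy engine, NetCDF3 classic), tabular data through pandas CSV.

## Bloom occurrence and phenology

The box-mean chlorophyll series is the unweighted mean over
non-missing cells whose centers lie in the region box; a time step
with no valid cell is a gap. Two thresholds are fitted on the full
record:

- occurrence: `mean + n_sd * SD`, with the *sample* standard deviation
  (ddof = 1), the conventional choice for climatological records, and
  `n_sd = 1` by default;
- phenology: the long-term median.

Presence is strict exceedance (`>`); ties and gaps never qualify.
Occurrences are attributed to austral seasons (Jul 1–Jun 30, labelled
by the calendar year of the July) so that the Southern Hemisphere
summer, which spans New Year, is one season. Per season, the bloom
event runs from the first to the last exceedance of the median
threshold; interior dips or cloud/ice gaps do not split the event,
because the seasonal bloom bounded by first/last valid exceedance is
the quantity of interest and satellite gaps are pervasive at these
latitudes. Duration is end − onset in days; the monthly distribution
of occurrences uses each time bin's start date.

## De-seasoning, composites, lagged correlation

The climatology is the per-pixel mean over years for each calendar bin
— 12 months for monthly data or 46 eight-day bins per year (day-of-year
// 8, with the final short bin folded into bin 45) — ignoring missing
values and recording sample counts. Anomaly = value − bin climatology;
a pixel-bin with no valid samples propagates as missing. By
construction per-bin anomaly means vanish on gap-free data
(to ~1e-16; tests require 1e-10), and the all-times composite is zero.

Composite maps are per-pixel means of anomalies over a selected time
subset (bloom-present months, or their complement), reporting the
selected fraction of the record. Count-weighted present and absent
composites sum to zero per pixel.

Lagged correlation maps pair response anomalies A(t) with forcing
anomalies B(t − lag), per pixel, for lag ≥ 0 (forcing leads). Pearson
r is computed from pairwise-complete sums, vectorized across the grid;
a pixel/lag needs ≥ 3 valid pairs and nonzero variance, else r is NaN.
Significance is a two-sided t test with the pairwise n; map-wide
Benjamini–Hochberg adjustment is available behind a flag but off by
default, since the headline statistic is a single boxed maximum rather
than a field-significance claim. The best-lag map is the argmax of |r|
per pixel; the reported extreme is the single largest-|r| value and
its lag. No detrending is applied beyond de-seasoning.

## Profile processing

- **Dark correction**: the in-situ dark signal is the 95th percentile
  of the channel between 400 and 600 m (window and percentile
  configurable), subtracted without clipping. A high percentile of the
  deep tail is deliberately conservative for fluorescence that decays
  to a floor contaminated by occasional deep particles.
- **De-spiking**: baseline = centered 3-point rolling mean (window
  shrinks at the edges); spikes = raw − baseline, so the pair sums
  back to the raw channel. Large positive residuals at depth flag
  discrete sinking particles/phytodetritus.
- **Calibration**: bottle depths are matched to the nearest sensor
  sample within a tolerance (default 5 m); bottle concentration is
  regressed on sensor signal by OLS with intercept (through-origin by
  flag); the fitted line converts the channel to mg m-3.
- **MLD, temperature criterion**: shallowest depth where
  |T − T_surface| > 0.04 °C, with the surface reference at the
  shallowest non-missing sample (gliders rarely reach 0 m) and the
  crossing linearly interpolated between bracketing samples. The
  absolute difference is used because summer Antarctic profiles often
  hold weak temperature inversions.
- **MLD, density criterion**: shallowest depth below 10 m where
  potential density exceeds its (interpolated) 10 m value by
  0.03 kg m-3, interpolated to the crossing. Both criteria are
  invariant to constant channel offsets and return "undetermined"
  (NaN) when never exceeded.
- **Inventories**: trapezoidal integral of a mg m-3 channel over
  [z_top, z_bottom] (default 0–100 m), with the shallowest value
  extended to z_top when the profile starts deeper and the lower bound
  interpolated when sampling passes it; result in g m-2. The rule is
  additive over adjacent ranges and linear in the channel.
- **ML POC:Chl**: ratio of depth-weighted (trapezoidal) means over
  [surface, MLD]; both channels must be calibrated.
- **High-POC screen**: keep profiles whose 0–100 m POC inventory
  strictly exceeds 15 g C m-2 *and* whose below-ML share of that
  inventory is ≤ 90%; the second clause excludes eddy-subduction
  events that inject organic matter below the mixed layer in one
  short-lived pulse. The density-criterion MLD is used for the split
  (consistent with float hydrography); profiles with undetermined MLD
  skip the subduction test but are retained and flagged. The below-ML
  share is computed on the 0–100 m inventory split at the MLD.

## Iron budgets

Demand (µmol Fe m-2) = POC (g C m-2) / M_C × (Fe:C) × 1e6, with
M_C = 12.011 g mol-1 (configurable; 12.0 changes the results by
< 0.1%). Preset ratios: 2.3×10⁻⁶ (Fe-replete) and 20×10⁻⁶
(Fe-deplete) mol:mol bracket the demand; 4.3×10⁻⁶ converts NPP. The
NPP conversion treats each series entry as one day of production and
sums daily demands (a day-sum convention; monthly-mean × days inputs
should be expanded to daily values first). The autotrophic adjustment
multiplies total POC by a fraction in (0, 1] — typically 0.2–0.3 —
before the conversion. Reported demands are rounded to 1 decimal;
raw values are retained on the budget object.

## Synthetic study conditions

The gridded generator builds each variable as a spatially uniform
calendar-bin sinusoid (chlorophyll peaking in January, zonal wind in
May, sea ice in September — the Southern Hemisphere phases the
de-seasoning must remove), plus additive box events, Gaussian noise,
and a completely-at-random missing mask of an exact cell count.
Injections are additive, so anomalies are known in closed form: an
amplitude A injected in one calendar bin of k of N years leaves
A(1 − k/N) in event years and −A·k/N elsewhere.

The default study grid (`recurring_bloom_config`) is 10 years of
monthly fields on a 13 × 13 half-degree/one-degree grid: bloom events
of +1.5 mg m-3 in Jan–Feb of 4 of the 10 austral seasons inside the
4–8° E / 67.8–68.4° S core box; each bloom season preceded by a
−3 m s-1 zonal wind anomaly (and −0.15 sea-ice anomaly) in Dec–Jan,
i.e. the forcing leads by exactly one month; noise SDs 0.05 mg m-3 /
0.5 m s-1 / 0.03, and 2% missing data. These sizes keep every stage
well-resolved while the whole analysis runs in seconds on one core.

The profile generator produces two-layer temperature/density steps at
a known MLD, a Gaussian bloom layer (chlorophyll in raw counts with a
dark offset; POC in mg m-3), optional spikes, and noise; the truth
carries the analytic Gaussian 0–100 m inventory (closed form via the
error function).

What the generator does *not* emulate — and therefore what passing
tests cannot show about real data: spatial structure of the seasonal
cycle and of cloud/ice gaps (missingness is not ice-correlated),
autocorrelated geophysical noise, mesoscale variability and fronts,
fluorescence quenching, sensor drift, and glider flight artifacts.
Truth-recovery results certify the statistical machinery, not
satellite retrieval or sensor physics.

## Numerical conventions and edge cases

- Strict inequalities throughout (presence, screen threshold, MLD
  criteria); a step exactly equal to a criterion delta is *not* a
  crossing.
- Criterion crossings and range boundaries are linearly interpolated;
  reporting the deeper bracketing sample instead is not currently
  exposed.
- Sample SD (ddof = 1) everywhere a spread is estimated.
- De-spike reconstruction (baseline + spikes = raw) is exact on
  instrument-scale data and is asserted bit-exact on the synthetic
  ensemble; for pathological inputs mixing magnitudes across hundreds
  of orders, float rounding caps fidelity at one ulp.
- Pearson maps clip r to [−1, 1] against rounding overshoot; p-values
  are NaN wherever r is undefined.
- All randomness flows from `numpy.random.default_rng(seed)`; equal
  seeds give bit-identical fields, masks and profiles.

## Known limitations

- The 8-day calendar uses fixed year-anchored bins; real 8-day
  satellite products restart binning each year the same way, but
  leap-day alignment can shift bin boundaries by a day.
- The box-mean is unweighted (no cos-latitude area weighting); over a
  0.6-degree-tall box the bias is negligible, but basin-scale boxes
  would want weighting.
- The NPP-based demand depends on the day-sum convention above;
  integrated demands from monthly products depend on how those months
  are expanded to days.
- Phenology exposes no smoothing; alternative phenology definitions
  (e.g. threshold-fraction-of-peak with smoothing) are out of scope.
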