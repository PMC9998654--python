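# weddellbloom

Analysis toolkit for recurrent open-ocean phytoplankton blooms in
seasonally ice-covered seas (eastern Weddell Gyre-style settings), for
biological oceanographers working with satellite ocean color,
reanalysis winds, sea-ice concentration, and glider / BGC-Argo optical
profiles.

The package implements four connected analyses:

1. **Bloom occurrence and phenology.** From a gridded chlorophyll-a
   record, the box-mean series Chl(t) over a study region is tested
   against a long-record threshold. Occurrence criterion:
   `Chl(t) > mean + n_sd * SD` (sample SD, full record, default
   `n_sd = 1`). Phenology criterion: exceedance of the long-term
   median, giving per-austral-season onset, end, duration (days) and
   peak. Austral seasons run Jul 1–Jun 30, so a January bloom belongs
   to the season begun the previous July.

2. **De-seasoned anomalies, composites and lagged correlations.**
   Anomalies are `x'(t) = x(t) − clim_b(t)` where `clim_b` is the
   per-pixel calendar-bin climatology (12 months or 46 eight-day bins).
   Composite maps average anomalies over bloom-present (or absent)
   times. Lagged correlation maps give the per-pixel Pearson r between
   chlorophyll anomalies at time t and a forcing anomaly (zonal wind,
   sea ice) at t − lag, with positive lag meaning the forcing leads;
   pairwise-complete observations, two-sided t-test p-values, optional
   Benjamini–Hochberg control.

3. **Optical profile processing.** Dark correction (95th percentile of
   the 400–600 m signal subtracted), de-spiking (3-point centered
   rolling-mean baseline; spikes = raw − baseline), OLS bottle
   calibration to mg m-3, mixed-layer depth by two criteria
   (|T − T_surface| > 0.04 °C; sigma > sigma(10 m) + 0.03 kg m-3, both
   interpolated to the crossing), trapezoidal 0–100 m inventories
   (g m-2), the mixed-layer POC:Chl ratio, and a high-POC float screen
   (inventory > 15 g C m-2, excluding profiles with > 90% of the POC
   below the mixed layer — an eddy-subduction signature).

4. **Fe:C iron budgets.** Areal iron demand
   `= POC [g C m-2] / 12.011 [g mol-1] × (Fe:C) × 1e6  [µmol Fe m-2]`,
   with bracketing ratios 2.3×10⁻⁶ (Fe-replete) and 20×10⁻⁶
   (Fe-deplete) mol:mol, a 4.3 µmol:mol mean ratio for NPP-based daily
   demand, and an autotrophic-fraction adjustment (phytoplankton are
   typically only 20–30% of total POC).

A synthetic-data module generates gridded archives and profiles with
known ground truth (injected bloom seasons, wind–chlorophyll coupling
at a configured lag, known MLD / inventories / dark offsets / spikes),
so every stage is testable by parameter recovery without external
downloads.

## Worked example

```python
import numpy as np
import weddellbloom as wb

# ten years of monthly chl / zonal wind / sea ice with four injected
# bloom seasons and a negative wind anomaly leading each by one month
fields, truth = wb.generate_gridded_dataset(wb.recurring_bloom_config(seed=1))

series = wb.compute_box_mean_series(fields["chl"], wb.BLOOM_CORE_BOX)
crit = wb.fit_bloom_criterion(series, "mean_plus_sd", n_sd=1)
occ = wb.detect_occurrences(series, crit)
stats = wb.occurrence_stats(occ, (series.index[0], series.index[-1]))
print(f"threshold = {crit.threshold:.3f} mg m-3")
print(f"bloom seasons: {stats.n_years_with_bloom} of {stats.n_years_total}")

anom_chl = wb.deseason(fields["chl"], wb.compute_climatology(fields["chl"]))
anom_wind = wb.deseason(fields["u_wind"], wb.compute_climatology(fields["u_wind"]))
res = wb.lagged_correlation_map(anom_chl, anom_wind, lags=[0, 1, 2])
inside = wb.BLOOM_CORE_BOX.mask(fields["chl"]).values
print(f"best lag in box = {np.nanmedian(res.best_lag.values[inside]):.0f} month(s), "
      f"mean r at lag 1 = {np.nanmean(res.r.sel(lag=1).values[inside]):.2f}")

low, high = wb.iron_demand_range(20.0)
print(f"Fe demand for 20 g C m-2: {low.demand_rounded}-{high.demand_rounded} umol Fe m-2")
```

prints

```
threshold = 1.089 mg m-3
bloom seasons: 4 of 11
best lag in box = 1 month(s), mean r at lag 1 = -0.78
Fe demand for 20 g C m-2: 3.8-33.3 umol Fe m-2
```

The detection threshold sits 1 SD above the record mean of the
box-mean series; all four injected bloom seasons (of the 11 austral
seasons the record touches) are recovered; the strongest
wind–chlorophyll coupling is found at the injected 1-month lead of the
easterly wind anomaly, with the injected negative sign; and building
20 g C m-2 of bloom carbon requires 3.8–33.3 µmol Fe m-2 depending on
the cellular Fe:C ratio.

The same stages are available from the shell:

```sh
bloom simulate --seed 1 --out sim.nc
bloom detect sim.nc --box 4,8,-68.4,-67.8 --method mean_plus_sd
bloom iron --poc 20 --ratios 2.3e-6,20e-6
bloom run --seed 1 --out report.json     # full pipeline, one JSON report
```

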