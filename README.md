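# fluorocal

QA/QC, temperature correction and calibration of high-frequency in-situ
chlorophyll-a (Chla) and phycocyanin (Phyco) fluorescence sensor data, for
limnologists and mesocosm experimentalists who need daily pigment
concentrations from noisy 1-minute fluorometer voltages.

In-situ fluorometers log voltages, not concentrations, and two years of
unattended deployment produce every classic artifact: daytime
non-photochemical quenching, negative bursts from power cuts, frozen
logger channels, snail-on-the-optics spikes, biofouling drift and
saturation at the gain ceiling. `fluorocal` implements the full workflow:

1. **Ingest** — logger ASCII → validated series, 1-min → 5-min medians.
2. **Clean** — fixed-order flagging protocol on night-time data
   (PAR ≤ 1): minimum-value floor, repeated-run removal, a scale-adaptive
   rate-of-change (ROC) despike (10 × MAD of recent first differences),
   and a rolling 48-h band filter (k = 1.2 envelope), with exact per-stage
   data-loss accounting.
3. **Correct** — temperature compensation to 20 °C with
   `F_r = F_m / (1 + ρ(T_m − T_r))`, ρ_chla = −0.014 °C⁻¹,
   ρ_phyco configurable (extract default −0.010 °C⁻¹).
4. **Calibrate** — per-sensor OLS of in-vitro Chla on nightly-median
   voltage, `invitro ~ chla_mV` or `invitro ~ chla_mV + phyco_mV`; the
   multiple form is gated on channel collinearity (|r| ≤ 0.6), and outliers
   are removed only when Cook's distance > 4/n **and** an MM-robust
   regression weight < 0.3 agree.
5. **Predict & evaluate** — daily "Equivalent-Chla" (µg L⁻¹) with
   censoring at the sensor ceiling (500 µg Chla L⁻¹), residuals, MAE /
   median AE, and annual/summer mean comparison against linearly
   interpolated in-vitro data (Student's t).

A ground-truthed synthetic mesocosm generator (24 tanks, 2 nutrient × 3
warming design, seasonal + bloom biomass, sensor cross-talk, fouling,
injected artifacts with an exact event log) makes every stage testable
without any data download. See `docs/methods.md` for the science and the
design decisions.

## Worked example

Simulate one high-nutrient tank for four months, run the whole pipeline,
and inspect the calibration:

```python
import datetime as dt
from fluorocal import default_scenario, run_synthetic_pipeline

cfg = default_scenario(seed=42, tank_ids=("A1",),
                       start=dt.date(2019, 4, 1), end=dt.date(2019, 7, 31))
res = run_synthetic_pipeline(cfg)

m = res.models["A1"]
print(f"tank A1: {m.kind} fit, n={m.n}, r2={m.r2:.3f}")
print(f"  equivalent-Chla = {m.intercept:.2f} + {m.b_chla:.4f} * chla_mV")
rep = res.cleaning_reports["A1"]
print(f"  night-time points removed: {rep.fraction_removed:.1%} "
      f"({rep.total_nighttime_points} points, {rep.equivalent_days_removed} full nights lost)")
pooled = res.agreement["pooled"]
print(f"  agreement vs in-vitro: MAE={pooled['mae']:.1f}, "
      f"median AE={pooled['median_ae']:.1f} ug/L over n={pooled['n']} dates")
```

prints

```
tank A1: simple fit, n=14, r2=0.980
  equivalent-Chla = -3.34 + 0.1369 * chla_mV
  night-time points removed: 13.2% (11270 points, 13 full nights lost)
  agreement vs in-vitro: MAE=14.4, median AE=10.1 ug/L over n=16 dates
```

The fitted slope (0.137 µg L⁻¹ per mV) sits above the nominal 0.1 because
the tank's cyanobacteria under-fluoresce in the Chla channel and residual
biofouling attenuates the signal — both absorbed by the calibration. The
13 % night-time loss is dominated by injected artifacts and saturated
(at-ceiling) runs in this bloom-heavy summer window; the removal counts per
stage are in `rep.removed_by_step`.

The same stages are available as a CLI for file-based work:

```sh
fluorocal simulate --seed 3 --tanks B1 --start 2019-06-01 --end 2019-07-05 --out sim/
fluorocal ingest --raw 'sim/logger_*.dat' --out ing/
fluorocal clean --in ing/sensors_5min.csv --par sim/par.dat --temp sim/temp_B1.dat --out cleaned/
fluorocal run --config run.yaml --out results/
```

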