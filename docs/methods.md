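# Methods

This note documents the models and procedures implemented in `fluorocal`,
the choices that were genuinely open, and what the synthetic tests do and
do not demonstrate about real sensor data.

## The measurement problem

In-situ fluorometers report a voltage proportional to pigment fluorescence,
not a concentration. Turning two years of 1-minute chlorophyll-a (Chla) and
phycocyanin (Phyco) voltages from a warming × nutrient mesocosm facility
into daily Chla concentrations ("Equivalent-Chla", µg L⁻¹) requires four
stages, each of which this package implements and tests:

1. **QA/QC** of the raw series (night-time selection, artifact removal);
2. **temperature compensation** to a 20 °C reference;
3. **per-sensor calibration** against spectrophotometric in-vitro Chla;
4. **evaluation** of the agreement between the two methods.

## Night-time selection and the cleaning protocol

Daytime fluorescence is depressed by non-photochemical quenching (NPQ), so
only night-time data are used. Night is defined by the co-deployed PAR
sensor reading at its floor (PAR ≤ 1 µmol m⁻² s⁻¹); PAR is held forward
onto the 5-min grid for at most 30 min, and points without PAR coverage are
conservatively treated as daytime.

Raw 1-min voltages are first aggregated to 5-min medians (left-closed bins
labelled by bin start; bins mixing gain settings are dropped — gain
transitions are untrustworthy). The cleaning protocol is then a fixed,
ordered sequence of flagging stages; points are never deleted, and each
removed point carries exactly one flag (its first cause), which makes the
data-loss accounting per stage exact:

| stage | rule | default |
|---|---|---|
| night | PAR ≤ `par_night_max` | 1 |
| floor | value < `min_mV` flagged | 0 mV |
| repeat | runs of ≥ `repeat_run_len` identical values | 6 |
| ROC | sequential rate-of-change despike | 10 × MAD, 7-day window |
| band | outside the rolling 48-h mean ± SD envelope | k = 1.2 |
| manual | operator-declared intervals | — |

**ROC filter.** Each point is differenced against the last *accepted*
point. The threshold is scale-free — `roc_mad_mult` × MAD of the accepted
first differences within a trailing 7-day window (the whole accepted
history when the window holds < 20) — so one configuration works across
tanks whose signals span two orders of magnitude. Two design choices
matter. First, differences spanning more than `roc_max_step` (1 h) are not
rate-of-change evidence: in night-only data adjacent retained points can be
14 h apart, and an overnight biomass change is not a spike; such gaps reset
the reference instead. Second, comparing against the last accepted point
(rather than the immediate predecessor) means the recovery point after a
spike is judged against the pre-spike level, so a spike costs exactly its
own points. An all-constant window (MAD 0) gets a machine-epsilon guard
scaled to the data values, so constant series and smooth ramps are never
flagged. The scan repeats until no new flags appear (max 5 passes).

**Rolling-band filter.** A point is flagged when it rises more than
`band_k` = 1.2 times above the rolling mean+SD envelope, or falls below the
(mean−SD)/k lower edge, over a centred, gap-aware 48-h window of retained
points (≥ 5 points, else no flag). The multiplicative envelope form is
essential: a filter that flags |x − m| > 1.2 s removes 15–25 % of *any*
stochastic series, because the standardised deviation from a window mean is
scale-free — no honest noise level can pass such a filter, and a two-year
deployment could not have survived it with single-digit data loss. The
multiplicative band instead fires only on order-of-magnitude excursions
(residual spikes, partial drop-outs) that the ROC stage missed.

Biofouling drift (gradual signal decline, jump after cleaning) is
deliberately *not* auto-corrected: bi-weekly sensor cleaning resets and
manual masks are the mechanism, and the calibration absorbs the mean
residual fouling into the slope.

Nightly medians assign points after midday to the night labelled by the
following calendar date, aligning each night with the next morning's bottle
sample; nights with fewer than 12 retained points (1 h) are dropped.

## Temperature compensation

Fluorescence yield falls as water warms. Both pigments are corrected with
the divisor form

    F_r = F_m / (1 + ρ (T_m − T_r)),   T_r = 20 °C

with ρ_chla = −0.014 per °C (the manufacturer-quoted 1.4 % per °C) and
ρ_phyco = −0.010 per °C as a commercial phycocyanin-extract default. The
divisor form is used for Chla as well as Phyco for internal consistency; it
agrees with the multiplicative 1 + 0.014·ΔT form to first order over the
±11 °C operating range. Site-specific coefficients are preferable where
they can be established — every cyanobacteria community has its own
temperature response — so ρ_phyco is an explicit config field, not a
constant. Temperature (30-min cadence) is interpolated linearly onto the
5-min grid; points whose bracketing observations are more than 2 h apart
are left uncorrected and flagged.

## Calibration

Nightly medians (mV, temperature-corrected) are paired with same-tank
in-vitro Chla by exact date (the sampling morning matched to the preceding
night). Sampling dates whose in-vitro concentration exceeds the sensor
ceiling (500 µg Chla L⁻¹ at X1 gain) are excluded — the sensor cannot
resolve them. Two model forms:

    simple:    invitro ~ chla_mV
    multiple:  invitro ~ chla_mV + phyco_mV

The multiple form is admissible only when |Pearson r| between the two
channels is ≤ 0.6: strong Chla fluorescence itself leaks into the Phyco
channel, and fitting two near-identical predictors is meaningless. In
`auto` mode the multiple form is chosen when a Phyco sensor exists, the
collinearity gate passes, and adjusted r² improves by more than 0.02.

**Outlier screening** is the conjunction of two criteria — a point is
dropped only when its Cook's distance exceeds 4/n in the OLS fit *and* its
MM-robust regression weight falls below 0.3 — and at most 20 % of points
may go. The conjunction is deliberately conservative: a real bloom sample
can look influential without being wrong. The MM estimator is implemented
in-package (no S/MM estimator exists in the installed Python stack):
a high-breakdown S-start (exact fits on 200 random p-subsets, candidate
with the smallest 50 %-breakdown bisquare M-scale wins, OLS included as a
candidate) followed by IRLS with bisquare weights at 95 % Gaussian
efficiency and the scale held fixed. The subset draw is internally seeded,
so the estimate is deterministic for a fixed input order; a test
cross-checks the weights against R's `MASS::rlm(method="MM")`.

Predictions are per-tank daily Equivalent-Chla. Inputs at or above the gain
ceiling are computed but marked `censored`; negative predictions are
clipped to zero and marked.

## Evaluation

Residuals are `invitro − equiv` (positive = sensor underestimates);
relative error is |residual| / invitro, with invitro = 0 dates excluded and
counted. Error summaries report MAE and median AE per tank and pooled, and
tail proportions split by residual sign. For the annual/summer comparison
the sparse in-vitro record is interpolated linearly to a daily grid (exact
at the sample dates, never extrapolated) and compared with daily
Equivalent-Chla using a two-sample pooled-variance Student t-test. Summer
is 1 June – 31 August (configurable; the convention of the facility's
region). Daily values of both series are strongly autocorrelated, so these
p-values are descriptive, not strictly inferential.

## The synthetic mesocosm generator

The generator exists so that every stage — and the full workflow — is
testable against known ground truth with no data download. It emulates a
24-tank facility: 2 nutrient levels (HN tanks A/D/F/G carry ≈ 25× the LN
biomass; LN mean 6.6 µg Chla L⁻¹) × 3 warming treatments (ambient, +3 °C,
+5 °C), October 2018 – August 2020 by default.

*Biomass* is a statistical process, not an ecosystem model: per tank,
log-biomass = seasonal sinusoid + stationary OU noise (τ = 5 d, σ = 0.10,
evolved continuously at 30-min nodes) + Poisson-timed Gaussian bloom pulses
(0.5 month⁻¹, 3–15 d, log-amplitude ≈ 1), split into independent "green"
and cyanobacterial components; the phycocyanin proxy is the cyano
component. Continuity at sub-daily scale matters: biomass that jumps
between daily nodes produces night-cluster level steps that no 48-h filter
can distinguish from artifacts, whereas real tank series are
trend-dominated at that scale. Bloom pulses are short enough that
biweekly/monthly bottle schedules provably miss some of them — the
mechanism behind interpolated in-vitro means underestimating summer
biomass, reproduced by construction in `bloom_miss_scenario`.

*Sensors* (1-min): channel yields with cross-talk — the Chla channel
responds weakly to cyanobacterial biomass (2 vs 10 mV per µg L⁻¹), the
Phyco channel has a small positive leakage from green Chla — times the
linear temperature factor, a static daytime NPQ depression (0.6; static is
sufficient because daytime data are discarded), multiplicative biofouling
decay (1 % d⁻¹, reset every 14 d at mid-morning cleaning), Gaussian noise
(CV 1 % + 1.5 mV floor), then injected artifacts (gross spikes of 3–10×
signal lasting 3–10 min, frozen repeated runs of 1–6 h, negative power-cut
bursts, outright gaps), then saturation at the gain ceiling (X1: 5000 mV,
X10: 500 mV; LN tanks run X10, HN tanks X1). Every artifact is logged
exactly once, so QA/QC flags can be scored unambiguously: a flagged bin
inside an artifact span is a true positive (a frozen run is untrustworthy
even while its held value still matches the signal); recall is scored only
over bins the artifact *materially* corrupted (aggregate shifted by more
than max(7.5 mV, 15 % of signal) against the artifact-free counterfactual);
bins saturated in the counterfactual are range-limited, not artifact-free,
and are excluded from false-flag accounting.

*In-vitro sampling*: HN tanks weekly in spring/summer, biweekly in autumn,
monthly in winter; LN tanks biweekly for the first three months, then
monthly; lognormal measurement noise (CV 5 %).

All randomness flows from one seed through per-tank, per-purpose spawned
generators, so outputs are identical for a fixed seed regardless of
simulation order.

**What passing synthetic tests does not show.** The generator's noise is
Gaussian and its biomass trends smooth; real series carry autocorrelated
patchiness, sensor drift the band filter cannot see, and community shifts
that change the fluorescence-to-Chla yield mid-season (the dominant real
error source a static calibration cannot absorb). Parameter-recovery
results here bound what the pipeline can do under its own assumptions; they
do not certify field accuracy.

## Problem sizes

The test suite runs scaled-down scenarios (2 tanks × 60–180 days for
end-to-end checks; the filter-oracle comparison uses 100 random series of
up to 5 000 points). `scripts/acceptance.py` runs six mixed HN/LN tanks for
a full calendar year for the agreement and data-loss figures, the four-tank
cyanobacteria scenario for the multiple-regression gain, two tanks × 6
months for artifact scoring, and single-tank year runs for slope recovery
and the bloom-miss mechanism; the whole script completes in a few minutes
on one CPU.

## Known limitations

- No model-based fouling-ramp detection; manual masks and cleaning resets
  only.
- No nonlinear or segmented calibration, and no DOC/turbidity covariates.
- The repeat filter keys on exactly-identical floats; a logger that
  re-quantises values could evade it.
- Censored (at-ceiling) days are flagged but still carry a computed value;
  summary means over heavily censored tanks are biased low by construction.
- The pooled t-test ignores autocorrelation; treat p-values as descriptive.
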