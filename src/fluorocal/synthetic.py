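"""Ground-truthed synthetic mesocosm datasets.

Emulates a 24-tank facility crossing two nutrient levels (LN tanks B, C, E,
H; HN tanks A, D, F, G — the HN treatment carries ~25x the biomass) with
three warming treatments (1 = ambient, 2 = +3 °C, 3 = +5 °C).  Each tank's
phytoplankton biomass is a statistical process, not an ecosystem model:
log-biomass is a seasonal sinusoid plus mean-reverting (OU) noise plus
Poisson-timed Gaussian bloom pulses of 3–15 days, split into a "green"
component and an independent cyanobacterial component whose phycocyanin is
the second fluorescence channel's target.  Bloom pulses are short enough
that biweekly/monthly bottle sampling provably misses some of them — the
mechanism behind interpolated in-vitro means underestimating summer
biomass.

Sensor voltages follow the physics the cleaning/calibration pipeline
assumes: channel yields with cross-talk (the Chla channel responds weakly
to cyanobacterial biomass; the Phyco channel has a small positive leakage
from green Chla), a linear fluorescence–temperature dependence, daytime
non-photochemical quenching, multiplicative biofouling decay reset on
cleaning days, Gaussian noise, then injected artifacts (gross spikes,
frozen repeated runs, negative power-cut bursts, outright gaps) and
saturation at the gain ceiling.  Every injected artifact is logged exactly
once, so QA/QC flags can be scored against truth without ambiguity.

All randomness flows from one integer seed through per-sensor spawned
generators, so outputs are byte-identical for a fixed seed regardless of
the order tanks are simulated in.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import EnvSeries, RawSensorSeries

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "SensorSim",
    "simulate_truth",
    "simulate_sensor",
    "simulate_all_sensors",
    "simulate_invitro",
    "truth_report",
    "default_scenario",
    "cyano_scenario",
    "bloom_miss_scenario",
    "write_scenario",
]

LETTERS = "ABCDEFGH"
HN_LETTERS = frozenset("ADFG")
WARMING_OFFSET = {"1": 0.0, "2": 3.0, "3": 5.0}  # AMB, A2, A2+


def all_tank_ids() -> list[str]:
    return [f"{letter}{num}" for letter in LETTERS for num in "123"]


def tank_nutrient(tank_id: str) -> str:
    return "HN" if tank_id[0] in HN_LETTERS else "LN"


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic run.

    Defaults mirror the mesocosm deployment the pipeline targets: a
    2018-10-01 – 2020-08-31 span, 1-min sensor logging, 10-min PAR, 30-min
    water temperature, LN tanks around 6.6 µg Chla L⁻¹ and HN tanks ~25x
    that, biweekly-to-weekly in-vitro sampling, 14-day sensor cleaning.
    """

    seed: int = 0
    start: dt.date = dt.date(2018, 10, 1)
    end: dt.date = dt.date(2020, 8, 31)
    tank_ids: tuple[str, ...] = tuple(all_tank_ids())

    # biomass process (log space, evolved continuously at 30-min nodes)
    ln_mean_ugL: float = 6.6
    hn_factor: float = 25.0
    seasonal_log_amplitude: float = 0.8
    seasonal_peak_doy: int = 196  # mid-July
    cyano_peak_doy: int = 235  # late August
    ou_log_sd: float = 0.10
    ou_tau_days: float = 5.0
    bloom_rate_per_month: float = 0.5
    bloom_log_amp_mean: float = 1.0
    bloom_log_amp_sd: float = 0.4
    bloom_duration_days: tuple[float, float] = (3.0, 15.0)
    cyano_frac_range_HN: tuple[float, float] = (0.1, 0.4)
    cyano_frac_range_LN: tuple[float, float] = (0.0, 0.1)
    #: (tank_id, date, log_amplitude, duration_days) pulses added verbatim
    forced_blooms: tuple[tuple[str, dt.date, float, float], ...] = ()

    # environment
    temp_annual_mean_C: float = 11.0
    temp_seasonal_amp_C: float = 8.5
    temp_diel_amp_C: float = 1.0
    temp_noise_sd_C: float = 0.2
    par_summer_max: float = 1500.0
    par_winter_max: float = 350.0

    # sensor model
    yield_chla_green: float = 10.0  # mV per µg L⁻¹
    yield_chla_cyano: float = 2.0  # weak Chla-channel response to cyanobacteria
    yield_phyco_cyano: float = 10.0
    yield_phyco_green: float = 1.0  # Chla → Phyco channel leakage
    rho_chla: float = -0.014
    rho_phyco: float = -0.010
    Tr: float = 20.0
    npq_day_factor: float = 0.6
    noise_cv: float = 0.01
    noise_floor_mV: float = 1.5
    gain_by_nutrient: tuple[tuple[str, str], ...] = (("LN", "X10"), ("HN", "X1"))
    gain_max_mV: tuple[tuple[str, float], ...] = (("X1", 5000.0), ("X10", 500.0))

    # artifacts (all off when enabled=False, including biofouling)
    artifacts_enabled: bool = True
    fouling_rate_per_day: float = 0.01
    cleaning_interval_days: int = 14
    spike_rate_per_day: float = 0.2
    spike_duration_min: tuple[int, int] = (3, 10)
    spike_mult: tuple[float, float] = (3.0, 10.0)
    spike_add_mV: float = 200.0
    repeat_rate_per_day: float = 0.05
    repeat_duration_min: tuple[int, int] = (60, 360)
    powercut_rate_per_day: float = 0.02
    powercut_duration_min: tuple[int, int] = (30, 360)
    powercut_value_mV: tuple[float, float] = (-300.0, -20.0)
    gap_rate_per_day: float = 0.05
    gap_duration_min: tuple[int, int] = (10, 240)

    # in-vitro sampling
    invitro_noise_cv: float = 0.05
    invitro_hour: int = 10

    def __post_init__(self) -> None:
        if (self.end - self.start).days < 30:
            raise ValueError("span must cover at least 30 days")
        for r in (self.bloom_rate_per_month, self.spike_rate_per_day,
                  self.repeat_rate_per_day, self.powercut_rate_per_day,
                  self.gap_rate_per_day, self.fouling_rate_per_day):
            if r < 0:
                raise ValueError("rates must be >= 0")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def gain_for(self, tank_id: str) -> str:
        return dict(self.gain_by_nutrient)[tank_nutrient(tank_id)]

    def gain_ceiling(self, gain: str) -> float:
        return dict(self.gain_max_mV)[gain]


def _tank_rng(cfg: ScenarioConfig, tank_id: str, stream: int) -> np.random.Generator:
    """Deterministic per-tank, per-purpose generator (order-independent)."""
    tank_code = LETTERS.index(tank_id[0]) * 10 + int(tank_id[1:])
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, tank_code, stream)))


@dataclass
class TankTruth:
    """Ground truth for one tank.

    ``paths`` holds the continuous biomass trajectories at 30-min nodes
    (columns ``green_ugL``, ``cyano_ugL``); ``daily`` samples them at the
    in-vitro sampling hour, one row per date.
    """

    tank_id: str
    paths: pd.DataFrame
    daily: pd.DataFrame  # date, green_ugL, cyano_ugL, chla_ugL, phyco_ugL
    cyano_frac: float

    def chla_at(self, dates) -> np.ndarray:
        s = pd.Series(self.daily["chla_ugL"].to_numpy(), index=self.daily["date"])
        return s.reindex(pd.Index(dates)).to_numpy()


@dataclass
class SyntheticTruth:
    """Ground truth for a whole scenario: biomass, environment, schedules."""

    cfg: ScenarioConfig
    tanks: dict[str, TankTruth]
    par: EnvSeries
    temp: dict[str, EnvSeries]
    cleaning_dates: list[dt.date]


def _seasonal(doy: np.ndarray, peak_doy: int) -> np.ndarray:
    return np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)


def _ou(n: int, sd: float, tau_days: float, dt_days: float,
        rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck path at fixed step (vectorised IIR)."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = np.exp(-dt_days / tau_days)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    shocks = rng.normal(0.0, innov_sd, size=n)
    shocks[0] = rng.normal(0.0, sd)
    x, _ = lfilter([1.0], [1.0, -a], shocks, zi=[0.0])
    return x


def _bloom_pulses(
    days: np.ndarray, cfg: ScenarioConfig, rng: np.random.Generator,
    forced: list[tuple[float, float, float]],
) -> np.ndarray:
    """Sum of Gaussian-in-time log-space pulses; forced = (day_coord, amp, dur)."""
    out = np.zeros(len(days))
    span_days = float(days[-1] - days[0]) if len(days) else 0.0
    months = span_days / 30.4375
    n_blooms = rng.poisson(cfg.bloom_rate_per_month * months)
    pulses = [
        (rng.uniform(days[0], days[-1]),
         abs(rng.normal(cfg.bloom_log_amp_mean, cfg.bloom_log_amp_sd)),
         rng.uniform(*cfg.bloom_duration_days))
        for _ in range(n_blooms)
    ]
    pulses.extend(forced)
    for t0, amp, dur in pulses:
        out += amp * np.exp(-(((days - t0) / (dur / 2.0)) ** 2))
    return out


def simulate_truth(cfg: ScenarioConfig) -> SyntheticTruth:
    """Generate continuous biomass truth plus PAR and per-tank temperature."""
    nodes = pd.date_range(
        pd.Timestamp(cfg.start), pd.Timestamp(cfg.end) + pd.Timedelta(days=1),
        freq="30min", inclusive="both",
    )
    day_coord = (nodes.asi8 - pd.Timestamp(cfg.start).value) / (24 * 3600 * 1e9)
    doy = nodes.dayofyear.to_numpy().astype(float) + nodes.hour.to_numpy() / 24.0
    dt_days = 1.0 / 48.0

    tanks: dict[str, TankTruth] = {}
    for tank_id in cfg.tank_ids:
        rng = _tank_rng(cfg, tank_id, stream=1)
        nutrient = tank_nutrient(tank_id)
        mean_total = cfg.ln_mean_ugL * (cfg.hn_factor if nutrient == "HN" else 1.0)
        lo, hi = (cfg.cyano_frac_range_HN if nutrient == "HN" else cfg.cyano_frac_range_LN)
        f_cyano = rng.uniform(lo, hi)
        forced = [
            ((pd.Timestamp(d) - pd.Timestamp(cfg.start)).days, amp, dur)
            for t, d, amp, dur in cfg.forced_blooms
            if t == tank_id
        ]
        comps = {}
        for comp, mean_c, peak in (
            ("green", mean_total * (1.0 - f_cyano), cfg.seasonal_peak_doy),
            ("cyano", mean_total * f_cyano, cfg.cyano_peak_doy),
        ):
            # draw every stream regardless, so the layout is identical
            # whether or not a component is active
            ou = _ou(len(nodes), cfg.ou_log_sd, cfg.ou_tau_days, dt_days, rng)
            pulses = _bloom_pulses(day_coord, cfg, rng, forced)
            if mean_c <= 0:
                comps[comp] = np.zeros(len(nodes))
                continue
            log_b = (
                np.log(mean_c)
                + cfg.seasonal_log_amplitude * _seasonal(doy, peak)
                + ou
                + pulses
            )
            comps[comp] = np.exp(log_b)
        paths = pd.DataFrame(
            {"green_ugL": comps["green"], "cyano_ugL": comps["cyano"]}, index=nodes
        )
        at_hour = paths[
            (paths.index.hour == cfg.invitro_hour) & (paths.index.minute == 0)
        ]
        daily = pd.DataFrame(
            {
                "date": at_hour.index.date,
                "green_ugL": at_hour["green_ugL"].to_numpy(),
                "cyano_ugL": at_hour["cyano_ugL"].to_numpy(),
                "chla_ugL": (at_hour["green_ugL"] + at_hour["cyano_ugL"]).to_numpy(),
                "phyco_ugL": at_hour["cyano_ugL"].to_numpy(),
            }
        )
        tanks[tank_id] = TankTruth(tank_id=tank_id, paths=paths, daily=daily,
                                   cyano_frac=f_cyano)

    par = _simulate_par(cfg)
    temp = {t: _simulate_temp(cfg, t) for t in cfg.tank_ids}
    cleaning_dates = [
        cfg.start + dt.timedelta(days=k)
        for k in range(0, cfg.n_days, cfg.cleaning_interval_days)
    ]
    return SyntheticTruth(cfg=cfg, tanks=tanks, par=par, temp=temp,
                          cleaning_dates=cleaning_dates)


def _daylength_hours(doy: np.ndarray) -> np.ndarray:
    # ~56° N: 7 h midwinter to 17.5 h midsummer
    return 12.25 + 5.25 * np.cos(2.0 * np.pi * (doy - 172) / 365.25)


def _simulate_par(cfg: ScenarioConfig) -> EnvSeries:
    """Diel PAR at 10-min cadence; night floor exactly 1."""
    idx = pd.date_range(
        pd.Timestamp(cfg.start), pd.Timestamp(cfg.end) + pd.Timedelta(days=1),
        freq="10min", inclusive="left",
    )
    doy = idx.dayofyear.to_numpy().astype(float)
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    daylen = _daylength_hours(doy)
    sunrise = 12.0 - daylen / 2.0
    sunset = 12.0 + daylen / 2.0
    frac = (hour - sunrise) / np.maximum(daylen, 1e-9)
    up = (frac > 0) & (frac < 1)
    season = 0.5 * (1 + _seasonal(doy, 172))
    amp = cfg.par_winter_max + (cfg.par_summer_max - cfg.par_winter_max) * season
    par = np.ones(len(idx))
    par[up] = np.maximum(1.0, amp[up] * np.sin(np.pi * frac[up]) ** 1.5)
    return EnvSeries(kind="par", series=pd.Series(par, index=idx, name="par"), cadence="10min")


def _simulate_temp(cfg: ScenarioConfig, tank_id: str) -> EnvSeries:
    """Seasonal + diel + warming-treatment water temperature at 30 min."""
    rng = _tank_rng(cfg, tank_id, stream=2)
    idx = pd.date_range(
        pd.Timestamp(cfg.start), pd.Timestamp(cfg.end) + pd.Timedelta(days=1),
        freq="30min", inclusive="left",
    )
    doy = idx.dayofyear.to_numpy().astype(float)
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    offset = WARMING_OFFSET[tank_id[1:]]
    T = (
        cfg.temp_annual_mean_C
        + cfg.temp_seasonal_amp_C * _seasonal(doy, 203)
        + cfg.temp_diel_amp_C * np.cos(2 * np.pi * (hour - 16) / 24.0)
        + offset
        + rng.normal(0.0, cfg.temp_noise_sd_C, size=len(idx))
    )
    return EnvSeries(kind="temperature", series=pd.Series(T, index=idx, name="temp_C"),
                     cadence="30min")


# ---------------------------------------------------------------------------
# sensor simulation


@dataclass
class SensorSim:
    """One simulated sensor: artifact-injected raw series plus bookkeeping."""

    raw: RawSensorSeries
    #: same grid as the pre-gap minute series, before artifact injection and
    #: saturation (noise included) — the counterfactual for scoring
    no_artifact_mV: pd.Series
    events: pd.DataFrame  # tank, pigment, type, start, end
    n_saturated: int
    ceiling_mV: float = float("inf")


def _interp_log_path(path: pd.Series, at: pd.DatetimeIndex) -> np.ndarray:
    """Log-linear interpolation of a 30-min biomass path onto minutes."""
    logd = np.log(np.maximum(path.to_numpy(), 1e-12))
    return np.exp(np.interp(at.asi8, path.index.asi8, logd))


def _fouling_factor(cfg: ScenarioConfig, idx: pd.DatetimeIndex,
                    cleaning_dates: list[dt.date]) -> np.ndarray:
    if not cfg.artifacts_enabled or cfg.fouling_rate_per_day == 0:
        return np.ones(len(idx))
    # optics are wiped mid-morning, so the post-cleaning jump falls in
    # daytime (discarded) data rather than inside a night
    clean_ts = np.array(
        [(pd.Timestamp(d) + pd.Timedelta(hours=10)).value for d in cleaning_dates],
        dtype=np.int64,
    )
    t_ns = idx.asi8
    pos = np.searchsorted(clean_ts, t_ns, side="right") - 1
    pos = np.clip(pos, 0, len(clean_ts) - 1)
    days_since = (t_ns - clean_ts[pos]) / (24 * 3600 * 1e9)
    days_since = np.maximum(days_since, 0.0)
    return np.exp(-cfg.fouling_rate_per_day * days_since)


def _draw_events(rng: np.random.Generator, rate_per_day: float, n_days: float,
                 idx: pd.DatetimeIndex, dur_min: tuple[int, int]) -> list[tuple[int, int]]:
    """(start, end) minute-index spans for Poisson-timed events."""
    n = rng.poisson(rate_per_day * n_days)
    spans = []
    for _ in range(n):
        s = int(rng.integers(0, len(idx)))
        d = int(rng.integers(dur_min[0], dur_min[1] + 1))
        spans.append((s, min(s + d, len(idx))))
    return spans


def simulate_sensor(truth: SyntheticTruth, tank_id: str, pigment: str) -> SensorSim:
    """Minute-cadence voltages for one sensor, with artifacts and event log."""
    cfg = truth.cfg
    tank = truth.tanks[tank_id]
    stream = 10 if pigment == "chla" else 11
    rng = _tank_rng(cfg, tank_id, stream=stream)

    idx = pd.date_range(
        pd.Timestamp(cfg.start), pd.Timestamp(cfg.end) + pd.Timedelta(days=1),
        freq="1min", inclusive="left",
    )
    green = _interp_log_path(tank.paths["green_ugL"], idx)
    cyano = _interp_log_path(tank.paths["cyano_ugL"], idx)

    if pigment == "chla":
        base = cfg.yield_chla_green * green + cfg.yield_chla_cyano * cyano
        rho = cfg.rho_chla
    else:
        base = cfg.yield_phyco_cyano * cyano + cfg.yield_phyco_green * green
        rho = cfg.rho_phyco

    T = np.interp(idx.asi8, truth.temp[tank_id].series.index.asi8,
                  truth.temp[tank_id].series.to_numpy())
    par = truth.par.series.reindex(idx, method="ffill").to_numpy()
    npq = np.where(par > 1.0, cfg.npq_day_factor, 1.0)
    fouling = _fouling_factor(cfg, idx, truth.cleaning_dates)

    signal = base * (1.0 + rho * (T - cfg.Tr)) * npq * fouling
    noise = signal * cfg.noise_cv * rng.normal(size=len(idx)) + \
        cfg.noise_floor_mV * rng.normal(size=len(idx))
    clean_mV = signal + noise

    value = clean_mV.copy()
    events = []
    keep = np.ones(len(idx), dtype=bool)
    if cfg.artifacts_enabled:
        n_days = cfg.n_days
        for s, e in _draw_events(rng, cfg.spike_rate_per_day, n_days, idx, cfg.spike_duration_min):
            amp = rng.uniform(*cfg.spike_mult) * max(float(np.median(signal[s:e])), 20.0) \
                + cfg.spike_add_mV
            value[s:e] = value[s:e] + amp
            events.append((tank_id, pigment, "spike", idx[s], idx[e - 1]))
        for s, e in _draw_events(rng, cfg.repeat_rate_per_day, n_days, idx, cfg.repeat_duration_min):
            value[s:e] = value[s]
            events.append((tank_id, pigment, "repeat", idx[s], idx[e - 1]))
        for s, e in _draw_events(rng, cfg.powercut_rate_per_day, n_days, idx,
                                 cfg.powercut_duration_min):
            value[s:e] = rng.uniform(*cfg.powercut_value_mV)
            events.append((tank_id, pigment, "powercut", idx[s], idx[e - 1]))
        for s, e in _draw_events(rng, cfg.gap_rate_per_day, n_days, idx, cfg.gap_duration_min):
            keep[s:e] = False
            events.append((tank_id, pigment, "gap", idx[s], idx[e - 1]))

    gain = cfg.gain_for(tank_id)
    ceiling = cfg.gain_ceiling(gain)
    saturated = value > ceiling
    value = np.minimum(value, ceiling)

    frame = pd.DataFrame({"value_mV": value[keep], "gain": gain}, index=idx[keep])
    raw = RawSensorSeries(sensor_id=f"{tank_id}_{pigment}", tank_id=tank_id,
                          pigment=pigment, frame=frame)  # type: ignore[arg-type]
    ev = pd.DataFrame(events, columns=["tank", "pigment", "type", "start", "end"])
    return SensorSim(
        raw=raw,
        no_artifact_mV=pd.Series(clean_mV, index=idx),
        events=ev,
        n_saturated=int(saturated.sum()),
        ceiling_mV=ceiling,
    )


def simulate_all_sensors(truth: SyntheticTruth) -> dict[tuple[str, str], SensorSim]:
    """Chla sensors in every tank; Phyco sensors in the HN tanks only."""
    sims = {}
    for tank_id in truth.cfg.tank_ids:
        sims[(tank_id, "chla")] = simulate_sensor(truth, tank_id, "chla")
        if tank_nutrient(tank_id) == "HN":
            sims[(tank_id, "phyco")] = simulate_sensor(truth, tank_id, "phyco")
    return sims


# ---------------------------------------------------------------------------
# in-vitro sampling


def _season(month: int) -> str:
    if month in (9, 10, 11):
        return "autumn"
    if month in (12, 1, 2):
        return "winter"
    return "spring_summer"


def _hn_schedule(start: dt.date, end: dt.date) -> list[dt.date]:
    """Biweekly in autumn, monthly in winter, weekly in spring/summer."""
    step = {"autumn": 14, "winter": 28, "spring_summer": 7}
    dates, d = [], start
    while d <= end:
        dates.append(d)
        d = d + dt.timedelta(days=step[_season(d.month)])
    return dates


def _ln_schedule(start: dt.date, end: dt.date) -> list[dt.date]:
    """Biweekly for the first three months, monthly thereafter."""
    dates, d = [], start
    while d <= end:
        dates.append(d)
        step = 14 if (d - start).days < 91 else 28
        d = d + dt.timedelta(days=step)
    return dates


def simulate_invitro(truth: SyntheticTruth) -> pd.DataFrame:
    """Scheduled bottle samples: daily truth x lognormal measurement noise."""
    cfg = truth.cfg
    rows = []
    sigma = np.sqrt(np.log(1.0 + cfg.invitro_noise_cv**2))
    for tank_id in cfg.tank_ids:
        rng = _tank_rng(cfg, tank_id, stream=3)
        sched = (_hn_schedule if tank_nutrient(tank_id) == "HN" else _ln_schedule)(
            cfg.start, cfg.end
        )
        tank = truth.tanks[tank_id]
        by_date = dict(zip(tank.daily["date"], tank.daily["chla_ugL"]))
        for d in sched:
            true_val = by_date.get(d)
            if true_val is None:
                continue
            noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma)) if sigma > 0 else 1.0
            rows.append({"tank_id": tank_id, "date": d, "chla_ugL": float(true_val * noise)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth scoring


def artifact_bins(
    sim: SensorSim,
    bin_minutes: int = 5,
    tol_mV: float = 7.5,
    rel_tol: float = 0.15,
) -> dict[str, set]:
    """Map injected artifacts to the 5-min bins they materially corrupted.

    ``touched``: bins overlapping any injected event span — flagging one of
    these is always a correct detection (a frozen run is untrustworthy even
    while its held value still matches the signal).  ``corrupted``: touched
    bins where the with-artifact aggregation differs from the
    counterfactual (no-artifact, ceiling-clipped) aggregation by more than
    max(``tol_mV``, ``rel_tol`` x local signal) — the median absorbs
    sub-threshold contamination, and a bump smaller than the band envelope
    width is not statistically detectable, so only these count against
    recall.  ``saturated``: bins whose counterfactual median sits at the
    gain ceiling; range-limited rather than artifact-free, excluded from
    false-flag accounting.
    """
    f = sim.raw.frame
    bins = f.index.floor(f"{bin_minutes}min")
    with_art = f["value_mV"].groupby(bins).median()
    cf = sim.no_artifact_mV.reindex(f.index).clip(upper=sim.ceiling_mV)
    without = cf.groupby(bins).median()
    diff = (with_art - without).abs()
    material = diff > np.maximum(tol_mV, rel_tol * without.abs())
    negative = set(with_art.index[with_art < 0])
    saturated = set(without.index[without >= sim.ceiling_mV])

    touched_by_type: dict[str, set] = {}
    for etype in ("spike", "repeat", "powercut"):
        spans = sim.events[sim.events["type"] == etype]
        touched: set = set()
        for _, r in spans.iterrows():
            lo = pd.Timestamp(r["start"]).floor(f"{bin_minutes}min")
            hi = pd.Timestamp(r["end"]).floor(f"{bin_minutes}min")
            touched.update(pd.date_range(lo, hi, freq=f"{bin_minutes}min"))
        touched_by_type[etype] = touched
    touched_all = set().union(*touched_by_type.values())
    corrupted = set(material.index[material]) & touched_all

    out: dict[str, set] = {
        "touched": touched_all,
        "corrupted": corrupted,
        "negative": negative,
        "saturated": saturated,
    }
    for etype, touched in touched_by_type.items():
        out[etype] = corrupted & touched
    return out


def score_artifact_flags(sim: SensorSim, flags: pd.Series) -> dict:
    """Score QA/QC flags for one sensor against the injected-artifact truth.

    Only night-time bins count (daytime is discarded by design).  Returns
    precision (flagged bins inside artifact spans / all flagged bins,
    saturated bins excluded), spike recall (materially corrupted spike bins
    flagged), negative recall (negative-aggregate bins flagged), and the
    false-flag rate over artifact-free unsaturated bins.
    """
    from .cleaning import Flag

    ab = artifact_bins(sim)
    night = (flags.to_numpy() & int(Flag.DAYTIME)) == 0
    night_bins = set(flags.index[night])
    flagged = set(flags.index[night & (flags.to_numpy() > 0)])
    sat = ab["saturated"]
    fl = flagged - sat
    touched = ab["touched"] & night_bins
    spikes = ab["spike"] & night_bins
    neg = ab["negative"] & night_bins
    clean_bins = night_bins - sat - touched

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "precision": ratio(len(fl & touched), len(fl)),
        "spike_recall": ratio(len(flagged & spikes), len(spikes)),
        "negative_recall": ratio(len(flagged & neg), len(neg)),
        "false_flag_rate": ratio(len(fl - touched), len(clean_bins)),
        "n_flagged": len(fl),
        "n_spike_bins": len(spikes),
        "n_negative_bins": len(neg),
        "n_night_bins": len(night_bins),
        "n_saturated_bins": len(sat & night_bins),
    }


def truth_report(
    truth: SyntheticTruth,
    models: dict[str, "object"],
    score_tables: dict[str, pd.DataFrame] | None = None,
) -> dict:
    """Recovery metrics versus ground truth.

    The true calibration slope for a tank follows from the channel yields:
    in-vitro Chla = green + cyano while chla_mV ≈ y_cg·green + y_cc·cyano,
    so for green-dominated tanks slope ≈ 1 / y_cg.
    """
    cfg = truth.cfg
    out: dict = {"slope_recovery": {}}
    for tank_id, model in models.items():
        true_slope = 1.0 / cfg.yield_chla_green
        b = getattr(model, "b_chla", None)
        if b is not None:
            out["slope_recovery"][tank_id] = {
                "true_slope": true_slope,
                "fitted_slope": float(b),
                "relative_error": float(abs(b - true_slope) / true_slope),
            }
    if score_tables:
        out.update(score_tables)
    return out


# ---------------------------------------------------------------------------
# canned scenarios


def default_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    return replace(ScenarioConfig(seed=seed), **overrides) if overrides else ScenarioConfig(seed=seed)


def cyano_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """A cyanobacteria-dominated HN scenario for the cross-channel question.

    Cyanobacterial biomass is large (frac ~0.5–0.7) and its dynamics are
    bloom-dominated rather than seasonal: green and cyano pulses are drawn
    independently, so the two fluorescence channels stay weakly collinear
    while the phyco channel carries a substantial share of the in-vitro
    Chla variance.
    """
    base = dict(
        seed=seed,
        tank_ids=("A1", "D1", "F1", "G1"),
        cyano_frac_range_HN=(0.5, 0.7),
        seasonal_log_amplitude=0.4,
        bloom_rate_per_month=1.0,
        ou_log_sd=0.15,
        start=dt.date(2019, 1, 1),
        end=dt.date(2019, 12, 31),
    )
    base.update(overrides)
    return ScenarioConfig(**base)


def bloom_miss_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """An LN tank with a strong mid-July bloom that monthly sampling misses.

    The LN schedule is monthly after its first three months; a forced
    8-day bloom centred between two sampling dates is invisible to the
    interpolated in-vitro record but fully visible to the daily sensor.
    """
    base = dict(
        seed=seed,
        tank_ids=("B1",),
        start=dt.date(2019, 1, 1),
        end=dt.date(2019, 12, 31),
        bloom_rate_per_month=0.0,
        forced_blooms=(("B1", dt.date(2019, 7, 15), 2.2, 8.0),),
    )
    base.update(overrides)
    return ScenarioConfig(**base)


# ---------------------------------------------------------------------------
# file export (logger-dialect ASCII)


def write_scenario(truth: SyntheticTruth, sims: dict, invitro: pd.DataFrame, outdir) -> dict:
    """Write logger-format ASCII + truth tables; returns the paths written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for (tank_id, pigment), sim in sims.items():
        f = sim.raw.frame
        df = pd.DataFrame(
            {
                "TIMESTAMP": f.index.strftime("%Y-%m-%d %H:%M:%S"),
                f"{tank_id}_{pigment}": f["value_mV"].to_numpy(),
                f"{tank_id}_{pigment}_gain": f["gain"].to_numpy(),
            }
        )
        p = outdir / f"logger_{tank_id}_{pigment}.dat"
        df.to_csv(p, index=False, float_format="%.6f")
        paths[f"raw_{tank_id}_{pigment}"] = p
    par = truth.par.series
    pd.DataFrame({"TIMESTAMP": par.index.strftime("%Y-%m-%d %H:%M:%S"), "par": par.to_numpy()}).to_csv(
        outdir / "par.dat", index=False, float_format="%.3f"
    )
    paths["par"] = outdir / "par.dat"
    for tank_id, env in truth.temp.items():
        s = env.series
        p = outdir / f"temp_{tank_id}.dat"
        pd.DataFrame({"TIMESTAMP": s.index.strftime("%Y-%m-%d %H:%M:%S"), "temp_C": s.to_numpy()}).to_csv(
            p, index=False, float_format="%.3f"
        )
        paths[f"temp_{tank_id}"] = p
    invitro.to_csv(outdir / "invitro.csv", index=False)
    paths["invitro"] = outdir / "invitro.csv"
    events = pd.concat([s.events for s in sims.values()], ignore_index=True)
    events.to_json(outdir / "events.json", orient="records", date_format="iso")
    paths["events"] = outdir / "events.json"
    for tank_id, tank in truth.tanks.items():
        p = outdir / f"truth_{tank_id}.csv"
        tank.daily.to_csv(p, index=False)
        paths[f"truth_{tank_id}"] = p
    return paths
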