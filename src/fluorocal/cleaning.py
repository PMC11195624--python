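"""Multi-step QA/QC of night-time fluorescence series.

In-situ fluorometry is only trustworthy at night (daytime readings are
depressed by non-photochemical quenching), and raw logger series carry
instrument artifacts: negative bursts from power cuts, frozen repeated
values, short gross spikes from snails or bubbles on the optics, and high
false variation.  The cleaning protocol is a fixed, ordered sequence of
stages, each flagging (never deleting) points:

    night selection → minimum-value floor → repeated-value runs
    → rate-of-change (ROC) filter → rolling 48-h band filter → manual masks

Every removed point carries exactly one flag (its first cause), so data-loss
accounting per stage is exact.  The ROC threshold is scale-free (MAD of
accepted first differences within a trailing window), which makes one
configuration work across tanks whose signals differ by two orders of
magnitude; differences spanning more than ``roc_max_step`` (the overnight
day gap in night-only data) are not rate-of-change evidence and reset the
reference point instead.  The band filter removes points falling outside a
multiplicative envelope around the centred rolling 48-h mean ± SD band:
more than k = 1.2 times above the upper edge or below the lower edge.
Gradual biofouling drift is deliberately not auto-corrected: cleaning-day
resets and manual masks are the mechanism for it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import EnvSeries, RawSensorSeries

__all__ = [
    "Flag",
    "CleaningConfig",
    "CleanSeries",
    "CleaningReport",
    "select_night",
    "floor_filter",
    "repeat_filter",
    "roc_filter",
    "rolling_band_filter",
    "apply_manual_masks",
    "nightly_median",
    "cleaning_report",
    "clean_pipeline",
]


class Flag(enum.IntFlag):
    """Removal causes, one bit per cleaning stage."""

    NONE = 0
    DAYTIME = 1
    BELOW_MIN = 2
    REPEAT = 4
    ROC = 8
    BAND = 16
    MANUAL = 32
    MIXED_GAIN = 64


#: stage order also defines first-cause priority in reports
STAGE_FLAGS = (
    Flag.DAYTIME,
    Flag.BELOW_MIN,
    Flag.REPEAT,
    Flag.ROC,
    Flag.BAND,
    Flag.MANUAL,
    Flag.MIXED_GAIN,
)


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds of the cleaning protocol.

    Defaults: PAR night threshold 1 (the deployed PAR sensor's night floor),
    minimum value 0 mV, repeated-run length 6 consecutive identical 5-min
    values, ROC threshold 10 × MAD of first differences over a trailing
    7-day window, band filter k = 1.2 over a centred 48-h window.
    """

    par_night_max: float = 1.0
    min_mV: float = 0.0
    repeat_run_len: int = 6
    roc_mad_mult: float = 10.0
    roc_window: pd.Timedelta = pd.Timedelta(days=7)
    roc_min_points: int = 20
    roc_max_passes: int = 5
    roc_max_step: pd.Timedelta = pd.Timedelta(hours=1)
    band_window: pd.Timedelta = pd.Timedelta(hours=48)
    band_k: float = 1.2
    band_min_points: int = 5
    manual_masks: tuple[tuple[str, tuple[pd.Timestamp, pd.Timestamp], str], ...] = ()

    def __post_init__(self) -> None:
        if self.band_k <= 0 or self.band_window <= pd.Timedelta(0):
            raise ValueError("band_k and band_window must be positive")
        if self.repeat_run_len < 2:
            raise ValueError("repeat_run_len must be >= 2")


@dataclass
class CleanSeries:
    """A 5-min series plus per-point removal flags.

    ``flags`` is an integer bitmask series aligned with ``series.frame``;
    retained points have flag 0.
    """

    series: RawSensorSeries
    flags: pd.Series
    manual_reasons: list[tuple[pd.Timestamp, pd.Timestamp, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.flags.index.equals(self.series.frame.index):
            raise ValueError("flags must align with the series index")

    @property
    def retained(self) -> pd.DataFrame:
        return self.series.frame[self.flags == 0]

    def retained_values(self) -> pd.Series:
        return self.series.frame.loc[self.flags == 0, "value_mV"]

    def copy(self) -> "CleanSeries":
        return CleanSeries(
            replace(self.series, frame=self.series.frame.copy()),
            self.flags.copy(),
            list(self.manual_reasons),
        )

    @staticmethod
    def fresh(series: RawSensorSeries) -> "CleanSeries":
        return CleanSeries(series, pd.Series(0, index=series.frame.index, dtype="int64"))


def select_night(series: RawSensorSeries, par: EnvSeries, cfg: CleaningConfig) -> CleanSeries:
    """Keep only night-time points (PAR ≤ threshold; sensor floor is 1).

    PAR is held forward onto the 5-min grid for at most 30 min; points with
    no PAR coverage are conservatively flagged as daytime.
    """
    if par.kind != "par":
        raise ValueError("select_night needs a PAR EnvSeries")
    cs = CleanSeries.fresh(series)
    on_grid = par.series.reindex(
        series.frame.index, method="ffill", tolerance=pd.Timedelta(minutes=30)
    )
    day = on_grid.isna() | (on_grid > cfg.par_night_max)
    cs.flags[day.to_numpy()] |= int(Flag.DAYTIME)
    return cs


def floor_filter(cs: CleanSeries, cfg: CleaningConfig) -> CleanSeries:
    """Flag retained values strictly below the minimum-data limit.

    Negative voltages are physically meaningless (power cuts, electronics);
    equality with the floor is retained.
    """
    out = cs.copy()
    keep = out.flags == 0
    bad = keep & (out.series.frame["value_mV"] < cfg.min_mV)
    out.flags[bad.to_numpy()] |= int(Flag.BELOW_MIN)
    return out


def repeat_filter(cs: CleanSeries, cfg: CleaningConfig) -> CleanSeries:
    """Flag maximal runs of identical consecutive retained values.

    Runs of length >= repeat_run_len indicate a frozen logger channel; the
    whole run is flagged.
    """
    out = cs.copy()
    keep = (out.flags == 0).to_numpy()
    vals = out.series.frame["value_mV"].to_numpy()
    pos = np.flatnonzero(keep)
    if len(pos) == 0:
        return out
    x = vals[pos]
    # run ids over the retained subsequence (NaN never joins a run)
    same = (x[1:] == x[:-1]) & ~np.isnan(x[1:]) & ~np.isnan(x[:-1])
    run_id = np.concatenate([[0], np.cumsum(~same)])
    _, counts = np.unique(run_id, return_counts=True)
    long_run = counts >= cfg.repeat_run_len
    bad = long_run[run_id]
    out.flags.iloc[pos[bad]] |= int(Flag.REPEAT)
    return out


def _mad(a: np.ndarray) -> tuple[float, float]:
    med = float(np.median(a))
    return med, float(np.median(np.abs(a - med)))


def _roc_offenders(
    t_ns: np.ndarray,
    x: np.ndarray,
    window_ns: int,
    mult: float,
    min_points: int,
    max_step_ns: int,
) -> np.ndarray:
    """Sequential rate-of-change scan over the retained subsequence.

    Each point is differenced against the last accepted point.  Differences
    spanning more than ``max_step_ns`` (the overnight gap in night-only
    series) are not rate-of-change evidence: the reference resets without a
    flag.  A point is flagged when its difference deviates from the median
    of the accepted differences in the trailing window by more than
    mult x their MAD (window widened to all accepted differences so far when
    it holds fewer than ``min_points``).  Comparing against the last
    *accepted* point means the recovery point after a spike is judged
    against the pre-spike level, so a single spike costs a single flag.
    """
    m = len(x)
    if m < 2:
        return np.empty(0, dtype=np.int64)
    eps = np.finfo(float).eps
    bad: list[int] = []
    acc_t = np.empty(m, dtype=np.int64)
    acc_d = np.empty(m, dtype=float)
    na = 0
    g = 0  # last accepted index
    for i in range(1, m):
        dt = t_ns[i] - t_ns[g]
        if dt > max_step_ns:
            g = i
            continue
        d = x[i] - x[g]
        lo = int(np.searchsorted(acc_t[:na], t_ns[i] - window_ns, side="right"))
        pool = acc_d[lo:na]
        if len(pool) < min_points:
            pool = acc_d[:na]
        if len(pool) >= 2:
            med, mad = _mad(pool)
            # guard floor covers rounding in d itself (~eps x value scale)
            guard = max(mad, eps * max(1.0, abs(x[i]) + abs(x[g])))
            if abs(d - med) > mult * guard:
                bad.append(i)
                continue
        g = i
        acc_t[na] = t_ns[i]
        acc_d[na] = d
        na += 1
    return np.asarray(bad, dtype=np.int64)


def roc_filter(cs: CleanSeries, cfg: CleaningConfig) -> CleanSeries:
    """Rate-of-change despiking over adjacent retained points.

    The threshold is scale-adaptive: mult x MAD of recent accepted first
    differences.  The scan repeats until no new flags appear (max
    ``roc_max_passes`` passes); an all-constant window (MAD 0) gets a
    machine-epsilon guard, so constant and smoothly ramping series are never
    flagged.
    """
    out = cs.copy()
    window_ns = int(cfg.roc_window.value)
    for _ in range(cfg.roc_max_passes):
        keep = (out.flags == 0).to_numpy()
        pos = np.flatnonzero(keep & out.series.frame["value_mV"].notna().to_numpy())
        t_ns = out.series.frame.index.asi8[pos]
        x = out.series.frame["value_mV"].to_numpy()[pos]
        bad = _roc_offenders(t_ns, x, window_ns, cfg.roc_mad_mult,
                             cfg.roc_min_points, int(cfg.roc_max_step.value))
        if len(bad) == 0:
            break
        out.flags.iloc[pos[bad]] |= int(Flag.ROC)
    return out


def _band_offenders(
    t_ns: np.ndarray, x: np.ndarray, half_ns: int, k: float, min_points: int
) -> np.ndarray:
    """Indices outside k times the centred rolling mean ± SD envelope.

    A point is flagged when it rises more than k times above the upper band
    edge, x > k·(m + s), or falls below the lower edge, x < (m − s)/k,
    where m and s are the mean and SD of all retained points within
    ±window/2 of it (inclusive, the point itself included).  Windows with
    fewer than ``min_points`` members give no flag; a constant series flags
    nothing (x = m, s = 0, and the comparisons are strict).
    """
    bad = []
    for i in range(len(x)):
        lo = np.searchsorted(t_ns, t_ns[i] - half_ns, side="left")
        hi = np.searchsorted(t_ns, t_ns[i] + half_ns, side="right")
        w = x[lo:hi]
        if len(w) < min_points:
            continue
        m = float(np.mean(w))
        s = float(np.std(w, ddof=1))
        if x[i] > k * (m + s) or x[i] < (m - s) / k:
            bad.append(i)
    return np.asarray(bad, dtype=np.int64)


def rolling_band_filter(cs: CleanSeries, cfg: CleaningConfig) -> CleanSeries:
    """Flag points outside the rolling 48-h band envelope (single pass).

    Removes residual anomalies and false high variation: points more than
    ``band_k`` times above the rolling mean+SD envelope, or below the
    mean−SD envelope, over the centred 48-h window.  Statistics are
    gap-aware: computed over retained points within the time window, not a
    fixed count, because night-only series are irregular.
    """
    out = cs.copy()
    keep = (out.flags == 0).to_numpy()
    pos = np.flatnonzero(keep & out.series.frame["value_mV"].notna().to_numpy())
    t_ns = out.series.frame.index.asi8[pos]
    x = out.series.frame["value_mV"].to_numpy()[pos]
    bad = _band_offenders(t_ns, x, int(cfg.band_window.value) // 2, cfg.band_k, cfg.band_min_points)
    if len(bad):
        out.flags.iloc[pos[bad]] |= int(Flag.BAND)
    return out


def merge_intervals(
    intervals: Sequence[tuple[pd.Timestamp, pd.Timestamp]]
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    ivs = sorted((pd.Timestamp(a), pd.Timestamp(b)) for a, b in intervals)
    merged: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def apply_manual_masks(cs: CleanSeries, cfg: CleaningConfig,
                       reason_flag: Flag = Flag.MANUAL) -> CleanSeries:
    """Flag points inside operator-declared intervals for this tank.

    Covers biofouling episodes and unexplained sensor problems identified by
    inspection; overlapping masks are merged, reasons kept in the report.
    """
    out = cs.copy()
    tank = out.series.tank_id
    mine = [(iv, reason) for t, iv, reason in cfg.manual_masks if t == tank]
    if not mine:
        return out
    merged = merge_intervals([iv for iv, _ in mine])
    idx = out.series.frame.index
    keep = out.flags == 0
    for a, b in merged:
        hit = keep & (idx >= a) & (idx <= b)
        out.flags[hit.to_numpy()] |= int(reason_flag)
    for (a, b), reason in mine:
        out.manual_reasons.append((pd.Timestamp(a), pd.Timestamp(b), reason))
    return out


def night_label(index: pd.DatetimeIndex) -> pd.Series:
    """Assign each timestamp to its night, labelled by the morning's date.

    Points after midday belong to the night labelled by the following
    calendar date, aligning nightly medians with next-morning in-vitro
    sampling.
    """
    dates = pd.Series(index.normalize(), index=index)
    evening = index.hour >= 12
    dates[evening] += pd.Timedelta(days=1)
    return dates.dt.date


def nightly_median(cs: CleanSeries, n_min: int = 12) -> pd.DataFrame:
    """Median of retained points per night (≥ ``n_min`` points, default 1 h).

    Returns a DataFrame with columns ``date``, ``median_mV``, ``n``.
    """
    r = cs.retained
    vals = r["value_mV"].dropna()
    if vals.empty:
        return pd.DataFrame(columns=["date", "median_mV", "n"])
    labels = night_label(pd.DatetimeIndex(vals.index))
    g = vals.groupby(labels.to_numpy())
    out = pd.DataFrame({"median_mV": g.median(), "n": g.size()})
    out = out[out["n"] >= n_min]
    out.index.name = "date"
    return out.reset_index()


@dataclass
class CleaningReport:
    """Per-stage removal accounting over night-time 5-min points."""

    removed_by_step: dict[str, int]
    total_nighttime_points: int
    fraction_removed: float
    equivalent_days_removed: int
    n_daytime: int

    def as_dict(self) -> dict:
        return {
            "removed_by_step": self.removed_by_step,
            "total_nighttime_points": self.total_nighttime_points,
            "fraction_removed": self.fraction_removed,
            "equivalent_days_removed": self.equivalent_days_removed,
            "n_daytime": self.n_daytime,
        }


def cleaning_report(cs: CleanSeries) -> CleaningReport:
    """Summarise data loss: per-stage counts, night-time fraction removed,
    and the number of nightly-median dates lost entirely."""
    flags = cs.flags.to_numpy()
    is_day = (flags & int(Flag.DAYTIME)) != 0
    night = ~is_day
    total_night = int(night.sum())
    removed_by_step: dict[str, int] = {}
    for f in STAGE_FLAGS:
        if f == Flag.DAYTIME:
            continue
        removed_by_step[f.name.lower()] = int(((flags[night] & int(f)) != 0).sum())
    removed = int((flags[night] != 0).sum())
    frac = removed / total_night if total_night else 0.0

    labels = night_label(cs.series.frame.index[night])
    lost_days = 0
    if len(labels):
        per_night = pd.Series(flags[night] != 0, index=labels.to_numpy()).groupby(level=0).all()
        lost_days = int(per_night.sum())
    return CleaningReport(
        removed_by_step=removed_by_step,
        total_nighttime_points=total_night,
        fraction_removed=frac,
        equivalent_days_removed=lost_days,
        n_daytime=int(is_day.sum()),
    )


def clean_pipeline(series: RawSensorSeries, par: EnvSeries, cfg: CleaningConfig) -> CleanSeries:
    """Run the fixed-order protocol: night → floor → repeat → ROC → band → manual."""
    cs = select_night(series, par, cfg)
    cs = floor_filter(cs, cfg)
    cs = repeat_filter(cs, cfg)
    cs = roc_filter(cs, cfg)
    cs = rolling_band_filter(cs, cfg)
    cs = apply_manual_masks(cs, cfg)
    return cs
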