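"""Agreement between Equivalent-Chla and in-vitro Chla.

Residuals are defined as invitro − equivalent, so a positive residual means
the sensor underestimates.  Relative error is |residual| / invitro (dates
with invitro = 0 are excluded and counted).  For the annual/summer mean
comparison, the sparse in-vitro record is linearly interpolated to a daily
grid (no extrapolation beyond the first/last sample) and compared against
the daily Equivalent-Chla with a two-sample pooled-variance Student t-test.
Daily values of these series are autocorrelated, so the p-values are
descriptive rather than strictly inferential.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import EquivalentChlaSeries

__all__ = [
    "AgreementMetrics",
    "MeansComparison",
    "residuals_and_relative_error",
    "error_summary",
    "interpolate_invitro_daily",
    "period_means_and_test",
    "summer_window",
    "annual_window",
]


@dataclass
class AgreementMetrics:
    """Per-date residuals and relative errors, possibly pooled over tanks."""

    table: pd.DataFrame  # tank, date, invitro_ugL, equiv_ugL, residual, relative_error
    n_zero_invitro: int


def residuals_and_relative_error(
    equiv: EquivalentChlaSeries | pd.DataFrame, invitro: pd.DataFrame
) -> AgreementMetrics:
    """Match tank-dates and compute residual = invitro − equiv and RE.

    ``equiv`` may be a single-tank EquivalentChlaSeries or a DataFrame with
    columns tank_id, date, equiv_chla_ugL for several tanks.
    """
    if isinstance(equiv, EquivalentChlaSeries):
        eq = equiv.frame[["date", "equiv_chla_ugL"]].copy()
        eq["tank_id"] = equiv.tank_id
    else:
        eq = equiv[["tank_id", "date", "equiv_chla_ugL"]].copy()
    merged = pd.merge(invitro, eq, on=["tank_id", "date"], how="inner")
    if merged.empty:
        raise ValueError("no matched tank-dates between equivalent and in-vitro series")
    merged["residual"] = merged["chla_ugL"] - merged["equiv_chla_ugL"]
    zero = merged["chla_ugL"] == 0
    merged["relative_error"] = np.where(
        zero, np.nan, np.abs(merged["residual"]) / merged["chla_ugL"]
    )
    table = merged.rename(columns={"chla_ugL": "invitro_ugL", "equiv_chla_ugL": "equiv_ugL"})[
        ["tank_id", "date", "invitro_ugL", "equiv_ugL", "residual", "relative_error"]
    ]
    return AgreementMetrics(table=table, n_zero_invitro=int(zero.sum()))


def error_summary(metrics: AgreementMetrics, threshold: float | None = None) -> dict:
    """MAE / median AE per tank and pooled, plus tail proportions.

    ``threshold`` defaults to the pooled MAE.  Tail proportions are computed
    separately among overestimates (residual < 0) and underestimates
    (residual > 0): the share of each group whose absolute error exceeds the
    threshold.
    """
    t = metrics.table
    if t.empty:
        raise ValueError("no residuals to summarise")
    ae = t["residual"].abs()
    pooled_mae = float(ae.mean())
    pooled_med = float(ae.median())
    if threshold is None:
        threshold = pooled_mae
    over = t[t["residual"] < 0]
    under = t[t["residual"] > 0]

    def tail(g: pd.DataFrame) -> float | None:
        if g.empty:
            return None
        return float((g["residual"].abs() > threshold).mean())

    per_tank = (
        t.assign(ae=ae)
        .groupby("tank_id")["ae"]
        .agg(mae="mean", median_ae="median", n="size")
        .reset_index()
    )
    return {
        "pooled": {
            "mae": pooled_mae,
            "median_ae": pooled_med,
            "n": int(len(t)),
            "mean_relative_error": float(t["relative_error"].mean(skipna=True)),
        },
        "per_tank": per_tank,
        "threshold": float(threshold),
        "prop_overestimates_above_threshold": tail(over),
        "prop_underestimates_above_threshold": tail(under),
        "n_overestimates": int(len(over)),
        "n_underestimates": int(len(under)),
    }


def interpolate_invitro_daily(
    invitro: pd.DataFrame,
    span: tuple[dt.date, dt.date],
    tank_id: str | None = None,
) -> pd.Series:
    """Daily series by straight-line interpolation between samples.

    Exact at the sample dates; never extrapolates beyond the first/last
    sample inside ``span``.  Raises with fewer than two samples in span.
    """
    inv = invitro if tank_id is None else invitro[invitro["tank_id"] == tank_id]
    inv = inv[(inv["date"] >= span[0]) & (inv["date"] <= span[1])].sort_values("date")
    if len(inv) < 2:
        raise ValueError("need >= 2 in-vitro samples in span to interpolate")
    d0 = inv["date"].iloc[0]
    xs = np.array([(d - d0).days for d in inv["date"]], dtype=float)
    ys = inv["chla_ugL"].to_numpy(dtype=float)
    grid_start = max(span[0], inv["date"].iloc[0])
    grid_end = min(span[1], inv["date"].iloc[-1])
    days = pd.date_range(grid_start, grid_end, freq="D").date
    xq = np.array([(d - d0).days for d in days], dtype=float)
    return pd.Series(np.interp(xq, xs, ys), index=pd.Index(days, name="date"))


def summer_window(year: int, start=(6, 1), end=(8, 31)) -> tuple[dt.date, dt.date]:
    """Summer period (default 1 June – 31 August)."""
    return dt.date(year, *start), dt.date(year, *end)


def annual_window(year: int) -> tuple[dt.date, dt.date]:
    return dt.date(year, 1, 1), dt.date(year, 12, 31)


@dataclass
class MeansComparison:
    """Method comparison over one calendar-defined window for one tank."""

    tank_id: str
    period: str
    mean_equiv: float | None
    mean_interp_invitro: float | None
    ci95_equiv: float | None
    ci95_interp: float | None
    t_statistic: float | None
    p_value: float | None
    n_equiv: int
    n_interp: int
    skipped_reason: str | None = None


def period_means_and_test(
    equiv_daily: pd.Series,
    interp_daily: pd.Series,
    window: tuple[dt.date, dt.date],
    period: str,
    tank_id: str = "",
    coverage_min: float = 0.8,
) -> MeansComparison:
    """Compare the two methods' means over a calendar window.

    Both daily series must cover at least ``coverage_min`` of the window,
    else the comparison is skipped with a reason.  Reports means, 95%
    normal-approximation CI half-widths, and a pooled-variance two-sided
    Student t-test on the daily values.
    """
    lo, hi = window
    n_days = (hi - lo).days + 1

    def clip(s: pd.Series) -> pd.Series:
        d = pd.Index(s.index)
        return s[(d >= lo) & (d <= hi)].dropna()

    a, b = clip(equiv_daily), clip(interp_daily)
    cov_a, cov_b = len(a) / n_days, len(b) / n_days
    if cov_a < coverage_min or cov_b < coverage_min:
        return MeansComparison(
            tank_id, period, None, None, None, None, None, None, len(a), len(b),
            skipped_reason=f"coverage {cov_a:.2f}/{cov_b:.2f} below {coverage_min}",
        )
    t_stat, p = stats.ttest_ind(a.to_numpy(), b.to_numpy(), equal_var=True)

    def half_ci(s: pd.Series) -> float:
        if len(s) < 2:
            return float("nan")
        return float(1.96 * s.std(ddof=1) / np.sqrt(len(s)))

    return MeansComparison(
        tank_id=tank_id,
        period=period,
        mean_equiv=float(a.mean()),
        mean_interp_invitro=float(b.mean()),
        ci95_equiv=half_ci(a),
        ci95_interp=half_ci(b),
        t_statistic=float(t_stat),
        p_value=float(p),
        n_equiv=len(a),
        n_interp=len(b),
    )
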