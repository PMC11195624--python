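"""Temperature compensation of fluorescence readings.

Fluorescence yield decreases as water warms, so raw voltages from different
nights are not comparable without compensation.  Both pigments are corrected
to a reference temperature with the divisor form

    F_r = F_m / (1 + ρ (T_m − T_r))

where F_m is the measured fluorescence at temperature T_m, T_r the reference
(20 °C) and ρ the temperature coefficient (negative: signal drops with
warming).  For chlorophyll-a the manufacturer-quoted sensitivity of 1.4 %
per °C gives ρ = −0.014; the same divisor form is used for both pigments for
internal consistency (it agrees with the multiplicative 1 + 0.014·ΔT form to
first order over the ±11 °C operating range).  The phycocyanin coefficient
ships with a commercial-extract default, but site-specific coefficients are
preferable where they can be established: each water body's cyanobacteria
community has its own temperature response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cleaning import CleanSeries, Flag
from .io import EnvSeries

__all__ = ["TempCorrectionParams", "correct_fluorescence", "correct_series", "TempCorrectionError"]


class TempCorrectionError(ValueError):
    pass


@dataclass(frozen=True)
class TempCorrectionParams:
    """Reference temperature (°C) and per-°C coefficients by pigment."""

    Tr: float = 20.0
    rho_chla: float = -0.014
    rho_phyco: float = -0.010  # commercial phycocyanin-extract coefficient
    operating_range_C: tuple[float, float] = (-1.0, 31.0)

    def __post_init__(self) -> None:
        lo, hi = self.operating_range_C
        for rho in (self.rho_chla, self.rho_phyco):
            for T in (lo, hi):
                if 1.0 + rho * (T - self.Tr) <= 0:
                    raise ValueError(
                        f"1 + rho*(T - Tr) must stay positive over {lo}..{hi} C (rho={rho})"
                    )

    def rho(self, pigment: str) -> float:
        if pigment == "chla":
            return self.rho_chla
        if pigment == "phyco":
            return self.rho_phyco
        raise ValueError(f"unknown pigment {pigment!r}")


def correct_fluorescence(Fm, Tm, pigment: str, params: TempCorrectionParams):
    """Return Fr = Fm / (1 + ρ·(Tm − Tr)); identity at Tm = Tr.

    Accepts scalars or arrays.  Monotone increasing in Tm for ρ < 0: the
    fluorescence lost at warmth is compensated upward.
    """
    rho = params.rho(pigment)
    denom = 1.0 + rho * (np.asarray(Tm, dtype=float) - params.Tr)
    if np.any(denom <= 0):
        bad = np.atleast_1d(np.asarray(Tm, dtype=float))[np.atleast_1d(denom) <= 0]
        raise TempCorrectionError(
            f"non-positive correction denominator at Tm={float(bad[0])} C"
        )
    out = np.asarray(Fm, dtype=float) / denom
    return float(out) if np.isscalar(Fm) or np.ndim(Fm) == 0 else out


def uncorrect_fluorescence(Fr, Tm, pigment: str, params: TempCorrectionParams):
    """Inverse map Fm = Fr · (1 + ρ·(Tm − Tr))."""
    rho = params.rho(pigment)
    return np.asarray(Fr, dtype=float) * (1.0 + rho * (np.asarray(Tm, dtype=float) - params.Tr))


def _interp_with_gap_mask(
    temp: pd.Series, at: pd.DatetimeIndex, max_gap: pd.Timedelta
) -> pd.Series:
    """Linear time interpolation of the 30-min temperature record onto the
    5-min grid; target points whose bracketing observations are more than
    ``max_gap`` apart (or missing) come back as NaN."""
    tt = temp.dropna().sort_index()
    if tt.empty:
        return pd.Series(np.nan, index=at)
    src_ns = tt.index.asi8
    at_ns = at.asi8
    vals = np.interp(at_ns, src_ns, tt.to_numpy(), left=np.nan, right=np.nan)
    # bracketing observation times for each target point
    right = np.searchsorted(src_ns, at_ns, side="left")
    left = np.searchsorted(src_ns, at_ns, side="right") - 1
    ok = (left >= 0) & (right < len(src_ns))
    gap_ok = np.zeros(len(at_ns), dtype=bool)
    li = np.clip(left, 0, len(src_ns) - 1)
    ri = np.clip(right, 0, len(src_ns) - 1)
    gap_ok[ok] = (src_ns[ri][ok] - src_ns[li][ok]) <= max_gap.value
    exact = np.isin(at_ns, src_ns)
    good = exact | (ok & gap_ok)
    out = np.where(good, vals, np.nan)
    return pd.Series(out, index=at)


def correct_series(
    cs: CleanSeries,
    temp: EnvSeries,
    params: TempCorrectionParams,
    max_gap: pd.Timedelta = pd.Timedelta(hours=2),
) -> CleanSeries:
    """Temperature-correct every retained value of a cleaned series.

    Temperature is interpolated linearly between the 30-min readings onto
    the series grid.  Points whose temperature gap exceeds ``max_gap`` are
    left uncorrected and flagged manual (reason ``no_temp``).  Applied before
    nightly medians.
    """
    if temp.kind != "temperature":
        raise ValueError("correct_series needs a temperature EnvSeries")
    out = cs.copy()
    keep = (out.flags == 0).to_numpy()
    idx = out.series.frame.index
    T = _interp_with_gap_mask(temp.series, idx, max_gap)
    no_temp = keep & T.isna().to_numpy()
    good = keep & ~T.isna().to_numpy()
    if good.any():
        corrected = correct_fluorescence(
            out.series.frame.loc[good, "value_mV"].to_numpy(),
            T.to_numpy()[good],
            out.series.pigment,
            params,
        )
        out.series.frame.loc[good, "value_mV"] = corrected
    if no_temp.any():
        out.flags[no_temp] |= int(Flag.MANUAL)
        spans = idx[no_temp]
        out.manual_reasons.append((spans.min(), spans.max(), "no_temp"))
    return out
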