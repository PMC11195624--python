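"""Per-sensor calibration of fluorescence voltages against in-vitro Chla.

Nightly voltage medians are paired with same-tank in-vitro chlorophyll-a
samples (the in-vitro sampling day matched to the preceding night's median)
and fitted by ordinary least squares:

    simple:    invitro_Chla ~ chla_mV
    multiple:  invitro_Chla ~ chla_mV + phyco_mV

The multiple model is only admissible when the two fluorescence channels are
not collinear (|Pearson r| ≤ 0.6): high Chla fluorescence itself leaks into
the phycocyanin channel, and fitting two near-identical predictors is
meaningless.  Sampling dates whose in-vitro concentration exceeds the sensor
ceiling (500 µg Chla L⁻¹ at X1) are excluded — the sensor cannot resolve
them, so they would only distort the fit.

Outlier screening is deliberately conservative: a calibration point is
dropped only when an OLS influence diagnostic (Cook's distance > 4/n) AND a
high-breakdown MM-robust regression weight (< w_min) both condemn it, and at
most ``max_frac`` of the points may go.  The conjunction protects legitimate
points — a single real bloom sample can look influential without being
wrong.  The model with and without the screened points is kept for
comparison.

Predictions are "Equivalent-Chla" (µg L⁻¹).  Inputs at or above the gain
ceiling are computed but marked censored; negative predictions are clipped
to zero and marked.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .io import SensorSpec

__all__ = [
    "CalibrationError",
    "CalibrationPairs",
    "CalibrationModel",
    "EquivalentChlaSeries",
    "pair_points",
    "collinearity",
    "fit_calibration",
    "mm_estimate",
    "detect_outliers",
    "fit_with_outlier_screen",
    "calibrate_tank",
    "predict_equivalent",
]

COLLINEARITY_MAX = 0.6
N_MIN = 8


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationPairs:
    """Matched (nightly median mV, in-vitro µg L⁻¹) rows for one tank."""

    tank_id: str
    rows: pd.DataFrame  # columns: date, chla_med_mV, [phyco_med_mV], invitro_ugL
    excluded: pd.DataFrame  # columns: date, reason

    @property
    def has_phyco(self) -> bool:
        return "phyco_med_mV" in self.rows.columns and self.rows["phyco_med_mV"].notna().all()

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class CalibrationModel:
    """Fitted calibration: Equivalent-Chla = a + b_chla·mV (+ b_phyco·mV)."""

    tank_id: str
    kind: str  # "simple" | "multiple"
    intercept: float
    b_chla: float
    b_phyco: float | None
    r2: float
    adj_r2: float
    n: int
    stderr: dict[str, float]
    collinearity_r: float | None
    outlier_dates: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def predict(self, chla_mV: np.ndarray, phyco_mV: np.ndarray | None = None) -> np.ndarray:
        y = self.intercept + self.b_chla * np.asarray(chla_mV, dtype=float)
        if self.kind == "multiple":
            if phyco_mV is None:
                raise CalibrationError("multiple-regression model needs a phyco series")
            y = y + self.b_phyco * np.asarray(phyco_mV, dtype=float)
        return y

    def to_json(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in (
            "tank_id", "kind", "intercept", "b_chla", "b_phyco", "r2", "adj_r2",
            "n", "stderr", "collinearity_r", "diagnostics")}
        d["outlier_dates"] = [str(x) for x in self.outlier_dates]

        def fallback(o):
            try:
                return float(o)
            except (TypeError, ValueError):
                return str(o)

        Path(path).write_text(json.dumps(d, indent=2, default=fallback))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def pair_points(
    chla_nightly: pd.DataFrame,
    phyco_nightly: pd.DataFrame | None,
    invitro: pd.DataFrame,
    spec: SensorSpec,
    tank_id: str,
) -> CalibrationPairs:
    """Match in-vitro sampling dates to the preceding night's medians.

    In-vitro values above the sensor ceiling are excluded (``over_ceiling``);
    sampling dates without a usable nightly median are excluded
    (``no_sensor_data``).  Raises if nothing remains.
    """
    inv = invitro[invitro["tank_id"] == tank_id]
    chla_by_date = dict(zip(chla_nightly["date"], chla_nightly["median_mV"]))
    phyco_by_date = (
        dict(zip(phyco_nightly["date"], phyco_nightly["median_mV"]))
        if phyco_nightly is not None
        else None
    )
    rows, excluded = [], []
    for _, r in inv.iterrows():
        d, ugl = r["date"], float(r["chla_ugL"])
        if ugl > spec.chla_ceiling_ugL:
            excluded.append({"date": d, "reason": "over_ceiling"})
            continue
        if d not in chla_by_date:
            excluded.append({"date": d, "reason": "no_sensor_data"})
            continue
        row = {"date": d, "chla_med_mV": chla_by_date[d], "invitro_ugL": ugl}
        if phyco_by_date is not None:
            row["phyco_med_mV"] = phyco_by_date.get(d, np.nan)
        rows.append(row)
    rows_df = pd.DataFrame(rows)
    if rows_df.empty:
        raise CalibrationError(f"no calibration pairs for tank {tank_id}")
    return CalibrationPairs(
        tank_id=tank_id,
        rows=rows_df.reset_index(drop=True),
        excluded=pd.DataFrame(excluded, columns=["date", "reason"]),
    )


def collinearity(pairs: CalibrationPairs) -> float:
    """Pearson correlation between the two fluorescence channels.

    Returns NaN (undefined-collinearity marker; multiple regression is then
    disallowed) when either predictor has zero variance.
    """
    if "phyco_med_mV" not in pairs.rows.columns:
        raise CalibrationError("no phyco channel in pairs")
    sub = pairs.rows.dropna(subset=["chla_med_mV", "phyco_med_mV"])
    if len(sub) < 3:
        raise CalibrationError("need >= 3 paired points for collinearity")
    x, y = sub["chla_med_mV"].to_numpy(), sub["phyco_med_mV"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _design(pairs: CalibrationPairs, kind: str) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    cols = ["chla_med_mV"] + (["phyco_med_mV"] if kind == "multiple" else [])
    sub = pairs.rows.dropna(subset=cols + ["invitro_ugL"]).reset_index(drop=True)
    X = sm.add_constant(sub[cols].to_numpy(), has_constant="add")
    y = sub["invitro_ugL"].to_numpy()
    return X, y, sub


def fit_calibration(pairs: CalibrationPairs, kind: str, n_min: int = N_MIN) -> CalibrationModel:
    """Ordinary least squares fit of the chosen calibration form."""
    if kind not in ("simple", "multiple"):
        raise ValueError(f"kind must be simple|multiple, got {kind!r}")
    r = None
    if kind == "multiple":
        r = collinearity(pairs)
        if not np.isfinite(r):
            raise CalibrationError("collinearity undefined (zero-variance predictor); multiple regression disallowed")
        if abs(r) > COLLINEARITY_MAX:
            raise CalibrationError(
                f"multiple regression refused: |collinearity r| = {abs(r):.3f} > {COLLINEARITY_MAX}"
            )
    X, y, sub = _design(pairs, kind)
    if len(y) < n_min:
        raise CalibrationError(f"need >= {n_min} calibration points, have {len(y)}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CalibrationError("singular design matrix")
    res = sm.OLS(y, X).fit()
    names = ["intercept", "b_chla"] + (["b_phyco"] if kind == "multiple" else [])
    return CalibrationModel(
        tank_id=pairs.tank_id,
        kind=kind,
        intercept=float(res.params[0]),
        b_chla=float(res.params[1]),
        b_phyco=float(res.params[2]) if kind == "multiple" else None,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n=int(res.nobs),
        stderr={n_: float(se) for n_, se in zip(names, res.bse)},
        collinearity_r=r,
        diagnostics={"dates": list(sub["date"])},
    )


# ---------------------------------------------------------------------------
# MM-estimation (high-breakdown S-start + 95%-efficiency bisquare M-step)

_BISQ_C_S = 1.54764  # 50% breakdown S-scale tuning constant
_BISQ_B = 0.5  # consistency constant E_Phi[rho] for the above (rho with max 1)
_BISQ_C_M = 4.685  # 95% Gaussian efficiency for the M-step


def _rho_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    """Tukey bisquare rho normalised to max 1."""
    v = np.clip(u / c, -1.0, 1.0)
    return 1.0 - (1.0 - v**2) ** 3


def _bisquare_weights(u: np.ndarray, c: float) -> np.ndarray:
    w = np.zeros_like(u)
    inside = np.abs(u) < c
    w[inside] = (1.0 - (u[inside] / c) ** 2) ** 2
    return w


def _m_scale(r: np.ndarray, c: float = _BISQ_C_S, b: float = _BISQ_B,
             tol: float = 1e-10, max_iter: int = 200) -> float:
    """Solve (1/n) sum rho(r/s) = b for s (fixed-point iteration)."""
    s = np.median(np.abs(r)) / 0.6745
    if s == 0:
        return 0.0
    for _ in range(max_iter):
        m = float(np.mean(_rho_bisquare(r / s, c)))
        s_new = s * np.sqrt(m / b)
        if abs(s_new - s) <= tol * s:
            return float(s_new)
        s = s_new
    return float(s)


def mm_estimate(
    X: np.ndarray,
    y: np.ndarray,
    n_subsets: int = 200,
    seed: int = 19481,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> dict:
    """MM-robust linear regression.

    Stage 1 (S-start): exact fits on random p-point subsets; the candidate
    with the smallest bisquare M-scale of residuals (50% breakdown tuning)
    wins.  Stage 2 (M-step): IRLS with bisquare weights at 95% Gaussian
    efficiency, scale held fixed at the S-scale.  Returns coefficients,
    per-point weights, and the robust scale.  The subset draw is internally
    seeded, so the estimate is deterministic for fixed input order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise CalibrationError("too few points for a robust fit")
    rng = np.random.default_rng(seed)
    best_beta, best_scale = None, np.inf
    # include the OLS solution as one candidate (helps clean data)
    candidates = [np.linalg.lstsq(X, y, rcond=None)[0]]
    for _ in range(n_subsets):
        idx = rng.choice(n, size=p, replace=False)
        try:
            beta = np.linalg.solve(X[idx], y[idx])
        except np.linalg.LinAlgError:
            continue
        candidates.append(beta)
    for beta in candidates:
        s = _m_scale(y - X @ beta)
        if s < best_scale:
            best_scale, best_beta = s, beta
    if best_beta is None or not np.isfinite(best_scale):
        raise CalibrationError("MM S-stage failed")
    if best_scale == 0:
        # exact fit: all weights 1 on the fitted points
        r = y - X @ best_beta
        w = (np.abs(r) <= 1e-12 * max(1.0, float(np.max(np.abs(y))))).astype(float)
        return {"beta": best_beta, "weights": w, "scale": 0.0, "converged": True}
    beta = best_beta
    converged = False
    for _ in range(max_iter):
        u = (y - X @ beta) / best_scale
        w = _bisquare_weights(u, _BISQ_C_M)
        if w.sum() <= p:
            break
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ y)
        if np.max(np.abs(beta_new - beta)) <= tol * max(1.0, np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    u = (y - X @ beta) / best_scale
    return {
        "beta": beta,
        "weights": _bisquare_weights(u, _BISQ_C_M),
        "scale": best_scale,
        "converged": converged,
    }


def detect_outliers(
    pairs: CalibrationPairs,
    model: CalibrationModel,
    w_min: float = 0.3,
    max_frac: float = 0.2,
) -> list:
    """Dates condemned by BOTH Cook's distance (> 4/n) and MM weight (< w_min).

    At most ``max_frac`` of the points may be removed; beyond that the worst
    (largest Cook's distance) are kept within the cap with a warning.  If
    the robust fit fails, the influence criterion alone decides, with a
    warning.
    """
    X, y, sub = _design(pairs, model.kind)
    n = len(y)
    res = sm.OLS(y, X).fit()
    cooks = OLSInfluence(res).cooks_distance[0]
    influential = cooks > 4.0 / n
    try:
        mm = mm_estimate(X, y)
        low_weight = mm["weights"] < w_min
        if not mm["converged"] and mm["scale"] > 0:
            warnings.warn("MM M-step did not converge; weights from last iterate")
        flagged = influential & low_weight
    except CalibrationError:
        warnings.warn("robust fit failed; falling back to Cook's distance alone")
        flagged = influential
    idx = np.flatnonzero(flagged)
    cap = int(np.floor(max_frac * n))
    if len(idx) > cap:
        warnings.warn(
            f"outlier cap: {len(idx)} candidates exceed max_frac={max_frac}; keeping worst {cap}"
        )
        idx = idx[np.argsort(cooks[idx])[::-1][:cap]]
    return sorted(sub["date"].iloc[idx])


def fit_with_outlier_screen(
    pairs: CalibrationPairs, kind: str, n_min: int = N_MIN,
    w_min: float = 0.3, max_frac: float = 0.2,
) -> CalibrationModel:
    """Fit, screen outliers, refit without them; keep both fits' stats."""
    first = fit_calibration(pairs, kind, n_min=n_min)
    out_dates = detect_outliers(pairs, first, w_min=w_min, max_frac=max_frac)
    if not out_dates:
        return first
    kept = CalibrationPairs(
        tank_id=pairs.tank_id,
        rows=pairs.rows[~pairs.rows["date"].isin(out_dates)].reset_index(drop=True),
        excluded=pairs.excluded,
    )
    refit = fit_calibration(kept, kind, n_min=min(n_min, len(kept.rows)))
    refit.outlier_dates = list(out_dates)
    refit.diagnostics["r2_with_outliers"] = first.r2
    refit.diagnostics["r2_without_outliers"] = refit.r2
    return refit


def calibrate_tank(
    pairs: CalibrationPairs,
    kind: str = "auto",
    n_min: int = N_MIN,
    adj_r2_gain_min: float = 0.02,
) -> CalibrationModel:
    """Fit the calibration for one tank, choosing the model form.

    ``auto``: use multiple regression when a phyco channel exists, the
    channels pass the collinearity gate, and it improves adjusted r² by more
    than ``adj_r2_gain_min`` over the simple fit; else simple.
    """
    if kind != "auto":
        return fit_with_outlier_screen(pairs, kind, n_min=n_min)
    simple = fit_with_outlier_screen(pairs, "simple", n_min=n_min)
    if not pairs.has_phyco:
        return simple
    r = collinearity(pairs)
    if not np.isfinite(r) or abs(r) > COLLINEARITY_MAX:
        simple.diagnostics["multiple_rejected"] = "collinearity"
        simple.collinearity_r = None if not np.isfinite(r) else r
        return simple
    try:
        multiple = fit_with_outlier_screen(pairs, "multiple", n_min=n_min)
    except CalibrationError as exc:
        # e.g. outlier removal pushed the remaining points over the
        # collinearity gate; the simple fit stands
        simple.diagnostics["multiple_rejected"] = str(exc)
        simple.collinearity_r = r
        return simple
    if multiple.adj_r2 - simple.adj_r2 > adj_r2_gain_min:
        multiple.diagnostics["adj_r2_simple"] = simple.adj_r2
        return multiple
    simple.diagnostics["multiple_rejected"] = "no_adj_r2_gain"
    simple.collinearity_r = r
    return simple


@dataclass
class EquivalentChlaSeries:
    """Daily predicted Chla (µg L⁻¹) with censoring/clipping flags."""

    tank_id: str
    frame: pd.DataFrame  # columns: date, equiv_chla_ugL, censored, negative_clipped

    def series(self) -> pd.Series:
        return pd.Series(
            self.frame["equiv_chla_ugL"].to_numpy(), index=pd.Index(self.frame["date"])
        )


def predict_equivalent(
    model: CalibrationModel,
    daily: pd.DataFrame,
    spec: SensorSpec,
    gain: str | None = None,
) -> EquivalentChlaSeries:
    """Predict daily Equivalent-Chla from (corrected) nightly medians.

    ``daily`` needs columns ``date``, ``chla_med_mV`` (and ``phyco_med_mV``
    for a multiple model), optionally ``gain`` per row (else pass ``gain``).
    Inputs at/above the gain ceiling are computed but censored; negative
    predictions are clipped to 0 and marked.
    """
    chla = daily["chla_med_mV"].to_numpy(dtype=float)
    phyco = daily["phyco_med_mV"].to_numpy(dtype=float) if "phyco_med_mV" in daily else None
    if model.kind == "multiple" and phyco is None:
        raise CalibrationError("multiple-regression model needs a phyco series")
    y = model.predict(chla, phyco)
    gains = daily["gain"].astype(str).to_numpy() if "gain" in daily else np.full(len(daily), gain)
    if any(g in (None, "None") for g in gains):
        raise ValueError("gain must be given per row or as an argument")
    ceiling = np.array([spec.gain_max_mV(g) for g in gains])
    censored = chla >= ceiling
    clipped = y < 0
    y = np.where(clipped, 0.0, y)
    frame = pd.DataFrame(
        {
            "date": daily["date"].to_numpy(),
            "equiv_chla_ugL": y,
            "censored": censored,
            "negative_clipped": clipped,
        }
    )
    return EquivalentChlaSeries(tank_id=model.tank_id, frame=frame)
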