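"""Reading, writing and harmonising raw sensor and environment tables.

Dataloggers in mesocosm facilities emit delimited ASCII: a timestamp column
plus one voltage column per fluorescence sensor, with occasional missing-value
tokens, duplicated or shuffled rows, and per-sensor gain settings that change
over the deployment.  This module turns those files into tidy, validated
in-memory series and provides the 1-min → 5-min median aggregation that all
downstream QA/QC operates on.

Timestamps are timezone-naive local time throughout (the logger convention);
no DST arithmetic is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "IngestError",
    "LoggerDialect",
    "SensorSpec",
    "RawSensorSeries",
    "EnvSeries",
    "IngestReport",
    "read_logger_table",
    "read_env",
    "read_invitro",
    "aggregate_5min_median",
    "nominal_ugL",
    "write_tidy_csv",
    "read_tidy_csv",
    "write_cache",
    "read_cache",
]

Pigment = Literal["chla", "phyco"]
PIGMENTS = ("chla", "phyco")
GAINS = ("X1", "X10")


class IngestError(ValueError):
    """Raised when an input table violates the ingest contract."""


@dataclass(frozen=True)
class LoggerDialect:
    """How to parse one family of logger exports."""

    delimiter: str = ","
    timestamp_col: str = "TIMESTAMP"
    timestamp_format: str | None = None  # None: ISO-like, inferred
    missing_tokens: tuple[str, ...] = ("NAN", "", "-7999")
    default_gain: str = "X1"


@dataclass(frozen=True)
class SensorSpec:
    """Gain-dependent measurement ranges of the fluorometer.

    The X1 gain spans 0–5000 mV (nominally 0–500 µg Chla L⁻¹) and X10 spans
    0–500 mV (0–50 µg Chla L⁻¹); both imply the same nominal 0.1 µg L⁻¹ per
    mV.  ``chla_ceiling_ugL`` is the concentration above which no gain can
    resolve the signal, used to censor calibration points.
    """

    gain_range_mV: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"X1": (0.0, 5000.0), "X10": (0.0, 500.0)}
    )
    nominal_ugL_per_mV: float = 0.1
    chla_ceiling_ugL: float = 500.0

    def __post_init__(self) -> None:
        for gain, (lo, hi) in self.gain_range_mV.items():
            if hi <= lo:
                raise ValueError(f"empty gain range for {gain!r}")
        x1_hi = self.gain_range_mV.get("X1", (0.0, 5000.0))[1]
        implied = x1_hi * self.nominal_ugL_per_mV
        if not np.isclose(implied, self.chla_ceiling_ugL, rtol=1e-6):
            raise ValueError(
                f"chla_ceiling_ugL={self.chla_ceiling_ugL} inconsistent with "
                f"X1 range x nominal factor ({implied})"
            )

    def gain_max_mV(self, gain: str) -> float:
        return self.gain_range_mV[gain][1]


@dataclass
class RawSensorSeries:
    """One sensor's voltage time series with pigment and gain metadata.

    ``frame`` is indexed by a strictly increasing timezone-naive
    DatetimeIndex and has columns ``value_mV`` (float, NaN = gap) and
    ``gain`` (str, defined for every row).
    """

    sensor_id: str
    tank_id: str
    pigment: Pigment
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.pigment not in PIGMENTS:
            raise ValueError(f"unknown pigment {self.pigment!r}")
        idx = self.frame.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("frame must be indexed by timestamps")
        if idx.tz is not None:
            raise ValueError("timestamps must be timezone-naive")
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing after ingest")
        if len(idx) != idx.nunique():
            raise ValueError("duplicate timestamps")
        if self.frame["gain"].isna().any():
            raise ValueError("gain must be defined for every timestamp")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def t(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def value_mV(self) -> pd.Series:
        return self.frame["value_mV"]


@dataclass
class EnvSeries:
    """PAR or water-temperature series.

    PAR is in µmol m⁻² s⁻¹ with the deployed sensor's night floor at 1;
    temperature is °C at a nominal 30-min cadence.
    """

    kind: Literal["par", "temperature"]
    series: pd.Series
    cadence: str | None = None

    def __post_init__(self) -> None:
        idx = self.series.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("series must be indexed by timestamps")
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        if self.kind == "par" and (self.series.dropna() < 0).any():
            raise IngestError("negative PAR value; the sensor floor is 1")


@dataclass
class IngestReport:
    """Counters accumulated while reading one file."""

    n_rows: int = 0
    n_missing_values: int = 0
    out_of_order: int = 0
    duplicate_identical_rows: int = 0


_SENSOR_COL = re.compile(r"^(?P<tank>[A-Za-z]\d+)_(?P<pigment>chla|phyco)$")


def _parse_timestamps(raw: pd.Series, fmt: str | None) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, format=fmt, errors="coerce")
    if parsed.isna().any():
        bad = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise IngestError(
            f"unparsable timestamp {raw.iloc[bad]!r} at data row {bad + 1}"
        )
    return pd.DatetimeIndex(parsed)


def read_logger_table(
    path: str | Path, dialect: LoggerDialect = LoggerDialect()
) -> tuple[list[RawSensorSeries], IngestReport]:
    """Parse one logger ASCII export into per-sensor series.

    Sensor columns are named ``<tank>_<pigment>`` (e.g. ``A1_chla``); an
    optional companion column ``<tank>_<pigment>_gain`` holds the per-row
    gain, otherwise ``dialect.default_gain`` applies.  Missing-value tokens
    become gaps; out-of-order rows are sorted (counted in the report);
    duplicate timestamps are allowed only when every sensor value agrees.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        dtype=str,
        keep_default_na=False,
        skipinitialspace=True,
    )
    if dialect.timestamp_col not in df.columns:
        raise IngestError(f"no timestamp column {dialect.timestamp_col!r} in {path.name}")
    report = IngestReport(n_rows=len(df))

    idx = _parse_timestamps(df[dialect.timestamp_col], dialect.timestamp_format)
    df = df.drop(columns=[dialect.timestamp_col]).set_index(idx)

    if len(df) > 1 and not df.index.is_monotonic_increasing:
        df = df.sort_index(kind="stable")
        report.out_of_order += 1
    if df.index.has_duplicates:
        dup = df.index.duplicated(keep="first")
        conflicting = False
        for ts in df.index[dup].unique():
            block = df.loc[[ts]]
            if (block.nunique() > 1).any():
                conflicting = True
                break
        if conflicting:
            raise IngestError(f"duplicate timestamp {ts} with conflicting values")
        report.duplicate_identical_rows += int(dup.sum())
        df = df[~dup]

    missing = set(dialect.missing_tokens)

    def to_float(col: pd.Series) -> pd.Series:
        vals = col.where(~col.isin(missing), np.nan)
        report.n_missing_values += int(vals.isna().sum() - col.isna().sum())
        return pd.to_numeric(vals, errors="raise").astype(float)

    out: list[RawSensorSeries] = []
    for col in df.columns:
        m = _SENSOR_COL.match(col)
        if m is None:
            continue
        values = to_float(df[col])
        gain_col = f"{col}_gain"
        if gain_col in df.columns:
            gain = df[gain_col].replace("", dialect.default_gain)
        else:
            gain = pd.Series(dialect.default_gain, index=df.index)
        frame = pd.DataFrame({"value_mV": values, "gain": gain})
        out.append(
            RawSensorSeries(
                sensor_id=col,
                tank_id=m["tank"],
                pigment=m["pigment"],  # type: ignore[arg-type]
                frame=frame,
            )
        )
    return out, report


def read_env(
    path: str | Path,
    kind: Literal["par", "temperature"],
    dialect: LoggerDialect = LoggerDialect(),
) -> EnvSeries:
    """Read a PAR or temperature table (timestamp + one numeric column)."""
    df = pd.read_csv(path, sep=dialect.delimiter, skipinitialspace=True)
    if dialect.timestamp_col not in df.columns:
        raise IngestError(f"no timestamp column {dialect.timestamp_col!r}")
    value_cols = [c for c in df.columns if c != dialect.timestamp_col]
    if len(value_cols) != 1:
        raise IngestError(f"expected exactly one value column, found {value_cols}")
    idx = _parse_timestamps(df[dialect.timestamp_col].astype(str), dialect.timestamp_format)
    s = pd.Series(
        pd.to_numeric(df[value_cols[0]], errors="coerce").to_numpy(),
        index=idx,
        name=value_cols[0],
    ).sort_index(kind="stable")
    cadence = None
    if kind == "temperature" and len(s) > 1:
        step = pd.Series(s.index).diff().mode()
        if len(step):
            cadence = f"{int(step.iloc[0].total_seconds() // 60)}min"
    return EnvSeries(kind=kind, series=s, cadence=cadence)


def read_invitro(path: str | Path, dialect: LoggerDialect = LoggerDialect()) -> pd.DataFrame:
    """Read in-vitro Chla samples; replicate rows per tank-date are averaged.

    Returns a DataFrame with columns ``tank_id``, ``date`` (datetime.date)
    and ``chla_ugL`` (µg L⁻¹, spectrophotometric), one row per tank-date.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, skipinitialspace=True)
    required = {"tank_id", "date", "chla_ugL"}
    if not required.issubset(df.columns):
        raise IngestError(f"in-vitro table needs columns {sorted(required)}")
    if df["tank_id"].isna().any() or (df["tank_id"].astype(str).str.strip() == "").any():
        raise IngestError("missing tank label in in-vitro table")
    df["chla_ugL"] = pd.to_numeric(df["chla_ugL"], errors="raise")
    if (df["chla_ugL"] < 0).any():
        raise IngestError("negative in-vitro Chla concentration")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    out = (
        df.groupby(["tank_id", "date"], as_index=False)["chla_ugL"]
        .mean()
        .sort_values(["tank_id", "date"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def aggregate_5min_median(raw: RawSensorSeries, bin_minutes: int = 5) -> RawSensorSeries:
    """Aggregate ≤5-min cadence data to left-closed 5-min-bin medians.

    Bins are labelled by their start.  The bin value is the median of its
    non-missing members; empty bins are gaps (no row emitted).  A bin's gain
    is its single gain; bins mixing X1 and X10 rows are dropped and counted
    in ``frame.attrs['mixed_gain_bins_dropped']`` (gain-transition samples
    are untrustworthy).
    """
    f = raw.frame
    bins = f.index.floor(f"{bin_minutes}min")
    value = f["value_mV"].groupby(bins).median()
    n_gains = f["gain"].groupby(bins).nunique()
    # mixed-gain bins are dropped below, so "first" is the single gain
    gain = f["gain"].groupby(bins).first()
    out = pd.DataFrame({"value_mV": value, "gain": gain})
    mixed = n_gains > 1
    n_mixed = int(mixed.sum())
    out = out[~mixed]
    out = out[out["value_mV"].notna()]
    agg = RawSensorSeries(raw.sensor_id, raw.tank_id, raw.pigment, out)
    agg.frame.attrs["mixed_gain_bins_dropped"] = n_mixed
    return agg


def nominal_ugL(value_mV: float | np.ndarray, gain: str, spec: SensorSpec) -> float | np.ndarray:
    """Nominal concentration implied by the printed gain ranges.

    Informational only — calibration always works in mV.
    """
    if gain not in spec.gain_range_mV:
        raise ValueError(f"unknown gain {gain!r}")
    return value_mV * spec.nominal_ugL_per_mV


# ---------------------------------------------------------------------------
# tidy output + cache

_TIDY_COLS = ["tank", "sensor", "pigment", "gain", "timestamp", "value_mV", "qc_flags"]


def _tidy_frame(series: Iterable[RawSensorSeries], flags: dict[str, pd.Series] | None = None) -> pd.DataFrame:
    rows = []
    for s in series:
        fl = None if flags is None else flags.get(s.sensor_id)
        rows.append(
            pd.DataFrame(
                {
                    "tank": s.tank_id,
                    "sensor": s.sensor_id,
                    "pigment": s.pigment,
                    "gain": s.frame["gain"].to_numpy(),
                    "timestamp": s.frame.index,
                    "value_mV": s.frame["value_mV"].to_numpy(),
                    "qc_flags": 0 if fl is None else fl.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=_TIDY_COLS)


def write_tidy_csv(series: Iterable[RawSensorSeries], path: str | Path,
                   flags: dict[str, pd.Series] | None = None) -> None:
    df = _tidy_frame(series, flags)
    df["timestamp"] = pd.DatetimeIndex(df["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False, float_format="%.17g")


def read_tidy_csv(path: str | Path) -> list[RawSensorSeries]:
    df = pd.read_csv(path, dtype={"tank": str, "sensor": str, "pigment": str, "gain": str},
                     float_precision="round_trip")
    out = []
    for sensor, g in df.groupby("sensor", sort=True):
        frame = pd.DataFrame(
            {"value_mV": g["value_mV"].to_numpy(), "gain": g["gain"].to_numpy()},
            index=pd.DatetimeIndex(pd.to_datetime(g["timestamp"])),
        )
        out.append(
            RawSensorSeries(
                sensor_id=str(sensor),
                tank_id=str(g["tank"].iloc[0]),
                pigment=str(g["pigment"].iloc[0]),  # type: ignore[arg-type]
                frame=frame,
            )
        )
    return out


def write_cache(series: Iterable[RawSensorSeries], path: str | Path) -> None:
    """Columnar binary cache (parquet) for fast re-reads of large runs."""
    _tidy_frame(series).to_parquet(path, index=False)


def read_cache(path: str | Path) -> list[RawSensorSeries]:
    df = pd.read_parquet(path)
    out = []
    for sensor, g in df.groupby("sensor", sort=True):
        frame = pd.DataFrame(
            {"value_mV": g["value_mV"].to_numpy(), "gain": g["gain"].to_numpy()},
            index=pd.DatetimeIndex(g["timestamp"]),
        )
        out.append(RawSensorSeries(str(sensor), str(g["tank"].iloc[0]),
                                   str(g["pigment"].iloc[0]), frame))  # type: ignore[arg-type]
    return out
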