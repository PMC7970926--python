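"""CSV dialects for the package's tabular inputs and outputs.

All tables are plain CSV with a header row.  Temperatures default to
degrees Celsius (column ``temperature_C``); a ``temperature_K`` column is
honoured when the unit tag is "K" and converted at the boundary.

Dialects::

    ter        temperature_C,time_min,ter[,se]
    alpha_beta temperature_C,alpha_per_Gy,beta_per_Gy2   (baseline row: 37 C)
    survival   dose_Gy,time_min,temperature_C,surviving_fraction
    schedule   duration_min,temperature_C
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .fitting import AlphaBetaDataset, TERDataset
from .thermal_dose import Schedule
from .units import to_celsius

__all__ = ["read_table", "write_ter_csv", "write_alpha_beta_csv", "write_schedule_csv"]

#: Temperature (C) flagging the no-heat baseline row in alpha/beta tables.
BASELINE_TEMP_C = 37.0

_DIALECTS = {
    "ter": ("time_min", "ter"),
    "alpha_beta": ("alpha_per_Gy", "beta_per_Gy2"),
    "survival": ("dose_Gy", "time_min", "surviving_fraction"),
    "schedule": ("duration_min",),
}


def _load_frame(path, dialect: str, unit: str) -> pd.DataFrame:
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    if df.empty:
        raise FormatError(f"{path}: no data rows")

    temp_col = f"temperature_{unit}"
    required = set(_DIALECTS[dialect]) | {temp_col}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)} for dialect {dialect!r}")

    errors = []
    for col in sorted(required):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        for i in bad:
            # +2: header line plus 1-based numbering
            errors.append(f"line {i + 2}: non-numeric value {df[col][i]!r} in column {col!r}")
        if df[col].isna().any():
            for i in df.index[df[col].isna()]:
                errors.append(f"line {i + 2}: missing value in column {col!r}")
        df[col] = coerced
    if errors:
        raise FormatError(f"{path}: " + "; ".join(errors))

    df["temperature_C"] = to_celsius(df[temp_col].to_numpy(), unit=unit)
    return df


def read_table(path, dialect: str, unit: str = "C", time: float | None = None):
    """Read and validate a CSV table, returning the matching typed object.

    Returns a :class:`TERDataset`, :class:`AlphaBetaDataset`,
    :class:`Schedule`, or (for ``survival``) a validated DataFrame.
    Row-level validation failures are reported with 1-based line numbers.
    ``time`` supplies the shared heating time for ``alpha_beta`` tables that
    carry no ``time_min`` column.
    """
    df = _load_frame(path, dialect, unit)
    if dialect == "ter":
        se = df["se"].to_numpy(dtype=float) if "se" in df.columns else None
        return TERDataset(
            temperature=df["temperature_C"].to_numpy(),
            time=df["time_min"].to_numpy(),
            ter=df["ter"].to_numpy(),
            se=se,
            label=str(path),
        )
    if dialect == "alpha_beta":
        base = df[df["temperature_C"] == BASELINE_TEMP_C]
        if base.empty:
            raise FormatError(
                f"{path}: no baseline row (temperature_C = {BASELINE_TEMP_C:g}) found"
            )
        if len(base) > 1:
            raise FormatError(f"{path}: multiple baseline rows")
        rest = df[df["temperature_C"] != BASELINE_TEMP_C]
        if rest.empty:
            raise FormatError(f"{path}: only the baseline row present")
        if "time_min" in df.columns:
            times = rest["time_min"].unique()
            if times.size != 1:
                raise FormatError(
                    f"{path}: alpha_beta tables must share one heating time, got {times}"
                )
            shared_time = float(times[0])
        elif time is not None:
            shared_time = float(time)
        else:
            raise FormatError(
                f"{path}: alpha_beta table has no time_min column and no heating time was given"
            )
        return AlphaBetaDataset(
            temperature=rest["temperature_C"].to_numpy(),
            alpha=rest["alpha_per_Gy"].to_numpy(),
            beta=rest["beta_per_Gy2"].to_numpy(),
            alpha0=float(base["alpha_per_Gy"].iloc[0]),
            beta0=float(base["beta_per_Gy2"].iloc[0]),
            time=shared_time,
            label=str(path),
        )
    if dialect == "schedule":
        return Schedule(list(zip(df["duration_min"], df["temperature_C"])))
    # survival
    if (df["surviving_fraction"] <= 0).any() or (df["surviving_fraction"] > 1).any():
        bad = df.index[(df["surviving_fraction"] <= 0) | (df["surviving_fraction"] > 1)][0]
        raise FormatError(f"{path}: line {bad + 2}: surviving_fraction outside (0, 1]")
    return df[["dose_Gy", "time_min", "temperature_C", "surviving_fraction"]]


def write_ter_csv(d: TERDataset, path) -> None:
    cols = {"temperature_C": d.temperature, "time_min": d.time, "ter": d.ter}
    if d.se is not None and np.all(np.isfinite(d.se)):
        cols["se"] = d.se
    pd.DataFrame(cols).to_csv(path, index=False)


def write_alpha_beta_csv(d: AlphaBetaDataset, path) -> None:
    df = pd.DataFrame(
        {
            "temperature_C": np.concatenate([[BASELINE_TEMP_C], d.temperature]),
            "time_min": np.concatenate([[0.0], np.full(d.temperature.size, d.time)]),
            "alpha_per_Gy": np.concatenate([[d.alpha0], d.alpha]),
            "beta_per_Gy2": np.concatenate([[d.beta0], d.beta]),
        }
    )
    df.to_csv(path, index=False)


def write_schedule_csv(s: Schedule, path) -> None:
    pd.DataFrame(s.segments, columns=["duration_min", "temperature_C"]).to_csv(path, index=False)
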