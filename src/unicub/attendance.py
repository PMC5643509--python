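"""Hourly and daily nest attendance with the purity filter and covariates.

Nest attendance (incubation constancy) is the percentage of readings
scored as incubated within a window.  Windows are local-solar calendar
days or hours; a window contributes a record for an incubation type only
when at least 75% of its readings belong to that type, and the attendance
is then computed over that type's readings only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from unicub.data_model import (
    INCUBATION_TYPES,
    NestMetadata,
    SpeciesReference,
    TYPE_BIPARENTAL,
    TYPE_UNI_BI,
    TYPE_UNI_UNI,
    UniparentalPhase,
)
from unicub.extraction import IncubationStateSeries

ATTENDANCE_COLUMNS = (
    "nest_id",
    "date_local",
    "hour_local",
    "incubation_type",
    "attendance_pct",
    "purity_pct",
    "n_readings",
    "day_fraction_pct",
    "sine",
    "cosine",
)


@dataclass
class AttendanceParams:
    purity_threshold_pct: float = 75.0
    hatch_trim_h: float = 6.0
    chicks_trim_h: float = 24.0


def incubation_fraction(
    t: pd.Timestamp, incubation_start: pd.Timestamp, ref: SpeciesReference
) -> float:
    """Percent of the species-typical incubation period elapsed at ``t``.

    Values above 100 are permitted (incubation past the expected hatch).
    """
    period = pd.Timedelta(days=ref.typical_incubation_period_d)
    return float(100.0 * (t - incubation_start) / period)


def circadian_regressors(
    local_hour: Union[float, np.ndarray],
) -> tuple[Union[float, np.ndarray], Union[float, np.ndarray]]:
    """Sine/cosine of the time of day mapped to radians (2*pi*hour/24)."""
    h = np.asarray(local_hour, dtype=float)
    if np.any((h < 0.0) | (h >= 24.0)):
        raise ValueError("local_hour must lie in [0, 24)")
    radians = 2.0 * np.pi * h / 24.0
    sine, cosine = np.sin(radians), np.cos(radians)
    if np.isscalar(local_hour) or np.ndim(local_hour) == 0:
        return float(sine), float(cosine)
    return sine, cosine


def label_incubation_type(
    states: IncubationStateSeries,
    phases: Sequence[UniparentalPhase],
    ref: SpeciesReference,
) -> np.ndarray:
    """Per-reading incubation-type label.

    Readings of uniparental species are always uniparental; readings of
    biparental species are uniparental while inside a detected phase and
    biparental otherwise (including the excluded first regular bout).
    """
    n = len(states.df)
    if ref.uniparental_flag != "biparental":
        return np.full(n, TYPE_UNI_UNI, dtype=object)
    out = np.full(n, TYPE_BIPARENTAL, dtype=object)
    ts = pd.DatetimeIndex(states.df["timestamp_utc"])
    for p in phases:
        out[(ts >= p.start) & (ts < p.end)] = TYPE_UNI_BI
    return out


def _exclusion_mask(
    ts: pd.DatetimeIndex, meta: NestMetadata, params: AttendanceParams
) -> np.ndarray:
    """True for readings that must be dropped before windows are formed."""
    drop = np.zeros(len(ts), dtype=bool)
    if meta.hatch_start is not None:
        drop |= ts >= meta.hatch_start - pd.Timedelta(hours=params.hatch_trim_h)
    if meta.chicks_found is not None:
        drop |= ts >= meta.chicks_found - pd.Timedelta(hours=params.chicks_trim_h)
    for start, end in meta.excluded_spans:
        drop |= (ts >= start) & (ts < end)
    return drop


def _windowed_attendance(
    states: IncubationStateSeries,
    phases: Sequence[UniparentalPhase],
    meta: NestMetadata,
    ref: SpeciesReference,
    params: AttendanceParams,
    hourly: bool,
) -> pd.DataFrame:
    empty = pd.DataFrame(columns=list(ATTENDANCE_COLUMNS))
    if meta.eggs_remaining is not None and meta.eggs_remaining <= 1:
        return empty  # single-egg nests are excluded from attendance
    if meta.incubation_start is None:
        raise ValueError(f"nest {meta.nest_id}: incubation_start required for attendance")

    df = states.df
    if len(df) == 0:
        return empty
    ts_utc = pd.DatetimeIndex(df["timestamp_utc"])
    keep = ~_exclusion_mask(ts_utc, meta, params)
    if not keep.any():
        return empty

    local = pd.DatetimeIndex(df["timestamp_local"])[keep]
    incubated = df["incubated"].to_numpy(dtype=bool)[keep]
    types = label_incubation_type(states, phases, ref)[keep]

    work = pd.DataFrame(
        {
            "date_local": local.normalize(),
            "hour_local": local.hour if hourly else -1,
            "incubation_type": types,
            "incubated": incubated,
        }
    )
    keys = ["date_local", "hour_local", "incubation_type"]
    grouped = work.groupby(keys, sort=True, observed=True)["incubated"].agg(["size", "sum"])
    totals = work.groupby(["date_local", "hour_local"], sort=True)["incubated"].size()

    rows = []
    for (date, hour, itype), (n_type, n_inc) in grouped.iterrows():
        total = int(totals.loc[(date, hour)])
        purity = 100.0 * n_type / total
        if purity < params.purity_threshold_pct - 1e-9:
            continue
        if hourly:
            mid_local = date + pd.Timedelta(hours=hour + 0.5)
            mid_hour = (hour + 0.5) % 24.0
        else:
            mid_local = date + pd.Timedelta(hours=12)
            mid_hour = 12.0
        # window midpoint back in UTC for the day-fraction covariate
        offset = pd.Timedelta(hours=meta.longitude * 24.0 / 360.0)
        sine, cosine = circadian_regressors(mid_hour)
        rows.append(
            {
                "nest_id": meta.nest_id,
                "date_local": date,
                "hour_local": int(hour) if hourly else np.nan,
                "incubation_type": itype,
                "attendance_pct": 100.0 * n_inc / n_type,
                "purity_pct": purity,
                "n_readings": int(n_type),
                "day_fraction_pct": incubation_fraction(
                    mid_local - offset, meta.incubation_start, ref
                ),
                "sine": sine,
                "cosine": cosine,
            }
        )
    return pd.DataFrame(rows, columns=list(ATTENDANCE_COLUMNS))


def daily_attendance(
    states: IncubationStateSeries,
    phases: Sequence[UniparentalPhase],
    meta: NestMetadata,
    ref: SpeciesReference,
    params: Optional[AttendanceParams] = None,
) -> pd.DataFrame:
    """Per-local-day attendance records honouring the 75% purity rule."""
    return _windowed_attendance(states, phases, meta, ref, params or AttendanceParams(), hourly=False)


def hourly_attendance(
    states: IncubationStateSeries,
    phases: Sequence[UniparentalPhase],
    meta: NestMetadata,
    ref: SpeciesReference,
    params: Optional[AttendanceParams] = None,
) -> pd.DataFrame:
    """Per-local-hour attendance records honouring the 75% purity rule."""
    return _windowed_attendance(states, phases, meta, ref, params or AttendanceParams(), hourly=True)
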