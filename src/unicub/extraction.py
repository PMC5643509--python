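"""Per-reading incubation state, parent-labelled bouts and incubation start.

A reading counts as incubated when the (smoothed) nest temperature exceeds
a rolling reference of the surface temperature by at least ``margin_c``;
steep temperature slopes refine onsets and offsets so that the
post-departure cooling tail is not scored as incubation.  Maximal incubated
intervals become bouts, short internal off-gaps are merged, and RFID
detections label and split bouts by the attending parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from unicub.data_model import Bout, NestMetadata, RfidTrace, SpeciesReference, TemperatureTrace, UnusableTraceError


class EstimationError(ValueError):
    """Raised when no incubation-start estimation pathway has data."""


@dataclass
class ExtractionParams:
    """Tunable thresholds of the state classifier and bout segmenter.

    Defaults are calibrated on synthetic data; they are deliberately exposed
    because the original extraction thresholds are implementation details of
    the source scripts.
    """

    margin_c: float = 3.0
    surface_window_min: float = 10.0
    smooth_window_min: float = 5.0
    steep_slope_c_per_min: Optional[float] = 0.5  # None disables slope refinement
    #: a reading recovers to 'incubated' when the smoothed temperature is
    #: back within this many degrees of the running incubation plateau
    recovery_margin_c: float = 1.0
    recess_tolerance_min: float = 60.0
    rfid_assignment_window_min: float = 5.0

    def validate(self) -> None:
        for name in ("margin_c", "surface_window_min", "smooth_window_min",
                     "recess_tolerance_min", "rfid_assignment_window_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.steep_slope_c_per_min is not None and self.steep_slope_c_per_min <= 0:
            raise ValueError("steep_slope_c_per_min must be positive or None")


@dataclass
class IncubationStateSeries:
    """Per-reading incubation state aligned 1:1 with the temperature trace.

    ``df`` columns: ``timestamp_utc``, ``timestamp_local``, ``incubated``
    (bool), ``attending`` ('F'/'M'/'unknown'/'none'); ``attending != 'none'``
    iff ``incubated``.
    """

    nest_id: str
    df: pd.DataFrame


def local_solar_time(
    timestamp_utc: Union[pd.Timestamp, pd.Series, pd.DatetimeIndex],
    longitude: float,
) -> Union[pd.Timestamp, pd.Series, pd.DatetimeIndex]:
    """Shift UTC by the nest longitude: local = UTC + longitude * 24/360 hours."""
    if not -180.0 <= longitude <= 180.0:
        raise ValueError(f"longitude {longitude} out of [-180, 180]")
    offset = pd.Timedelta(hours=longitude * 24.0 / 360.0)
    return timestamp_utc + offset


def _sample_interval_s(ts: pd.Series) -> float:
    if len(ts) < 2:
        return 5.0
    diffs = ts.diff().dropna().dt.total_seconds()
    return float(diffs.median())


def classify_incubation(
    trace: TemperatureTrace,
    params: Optional[ExtractionParams] = None,
    longitude: float = 0.0,
) -> IncubationStateSeries:
    """Classify every reading of a temperature trace as incubated or not.

    With ``steep_slope_c_per_min=None`` the classifier reduces to the pure
    margin rule (reading incubated iff smoothed nest temperature exceeds the
    surface reference by ``margin_c``), which serves as the brute-force
    oracle mode.  Classification is idempotent: it depends only on the
    input trace and parameters.
    """
    params = params or ExtractionParams()
    params.validate()
    nest = trace.rows["nest_temp_c"].astype(float)
    surface = trace.rows["surface_temp_c"].astype(float)
    if len(trace.rows) == 0 or not np.isfinite(nest.to_numpy()).any():
        raise UnusableTraceError(f"trace {trace.nest_id} has no usable temperatures")

    ts = trace.rows["timestamp_utc"]
    dt_s = _sample_interval_s(ts)
    dt_min = dt_s / 60.0

    def _window(minutes: float) -> int:
        return max(1, int(round(minutes * 60.0 / dt_s)))

    surface_ref = surface.rolling(_window(params.surface_window_min), min_periods=1, center=True).median()
    w_smooth = _window(params.smooth_window_min)
    nest_smooth = nest.rolling(w_smooth, min_periods=1, center=True).mean() if w_smooth > 1 else nest

    margin_ok = ((nest_smooth - surface_ref) >= params.margin_c).to_numpy()
    margin_ok &= np.isfinite(nest.to_numpy()) & np.isfinite(surface.to_numpy())

    if params.steep_slope_c_per_min is None:
        incubated = margin_ok
    else:
        # Within each margin run, a steep fall marks a departure; the reading
        # stays off through the cooling tail and comes back on at a steep rise
        # or once the temperature has recovered to the incubation plateau
        # (tracked as a slow running average of attended readings).
        steep = params.steep_slope_c_per_min
        recover = params.recovery_margin_c
        vals = nest_smooth.to_numpy()
        slope = np.zeros(len(vals))
        if len(vals) > 1:
            slope[1:] = np.diff(vals) / dt_min  # backward difference: no lookahead
        incubated = np.zeros(len(vals), dtype=bool)
        for s, e in _incubated_runs(margin_ok):
            on = True
            plateau = vals[s]
            for i in range(s, e):
                if on:
                    if slope[i] <= -steep:
                        on = False
                    else:
                        plateau += 0.05 * (vals[i] - plateau)
                elif slope[i] >= steep or vals[i] >= plateau - recover:
                    on = True
                incubated[i] = on

    df = pd.DataFrame(
        {
            "timestamp_utc": ts.to_numpy(),
            "timestamp_local": local_solar_time(ts, longitude).to_numpy(),
            "incubated": incubated,
            "attending": np.where(incubated, "unknown", "none"),
        }
    )
    return IncubationStateSeries(trace.nest_id, df)


def _incubated_runs(incubated: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i, j) index runs of consecutive True."""
    if incubated.size == 0:
        return []
    padded = np.concatenate([[False], incubated, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def segment_bouts(
    states: IncubationStateSeries,
    rfid: Optional[RfidTrace] = None,
    params: Optional[ExtractionParams] = None,
    tag_sex: Optional[Mapping[str, str]] = None,
) -> list[Bout]:
    """Segment classified states into parent-labelled incubation bouts.

    Maximal incubated intervals are formed first; internal off-gaps shorter
    than ``recess_tolerance_min`` are merged.  Within each interval, RFID
    detections split the interval at change-overs (the first detection of a
    different tag) so that each bout is one parent's session; the attending
    parent is the tag with the majority of detections inside the bout, ties
    broken by the earlier-detected tag.  Intervals without detections get
    ``attending='unknown'``.
    """
    params = params or ExtractionParams()
    params.validate()
    df = states.df
    ts = pd.DatetimeIndex(df["timestamp_utc"])
    if len(ts) == 0:
        return []
    dt_s = _sample_interval_s(df["timestamp_utc"])
    dt = pd.Timedelta(seconds=dt_s)
    incubated = df["incubated"].to_numpy(dtype=bool)

    runs = _incubated_runs(incubated)
    if not runs:
        return []

    # merge runs separated by short off-gaps
    merged: list[tuple[int, int]] = [runs[0]]
    tol = pd.Timedelta(minutes=params.recess_tolerance_min)
    for s, e in runs[1:]:
        prev_s, prev_e = merged[-1]
        gap = ts[s] - (ts[prev_e - 1] + dt)
        if gap < tol:
            merged[-1] = (prev_s, e)
        else:
            merged.append((s, e))

    det_ts = pd.DatetimeIndex([])
    det_tags = np.array([], dtype=object)
    if rfid is not None and len(rfid.rows):
        det_ts = pd.DatetimeIndex(rfid.rows["timestamp_utc"])
        det_tags = rfid.rows["tag_id"].to_numpy(dtype=object)

    def _label(tags: np.ndarray, times: pd.DatetimeIndex) -> str:
        if len(tags) == 0:
            return "unknown"
        uniq, counts = np.unique(tags, return_counts=True)
        best = counts.max()
        candidates = set(uniq[counts == best])
        if len(candidates) > 1:
            # tie: the tag detected earliest wins
            for t in tags:
                if t in candidates:
                    winner = t
                    break
        else:
            winner = uniq[counts == best][0]
        if tag_sex is not None:
            return tag_sex.get(winner, "unknown")
        return "unknown" if winner is None else str(winner)

    bouts: list[Bout] = []
    for s, e in merged:
        start, end = ts[s], ts[e - 1] + dt
        inside = (det_ts >= start) & (det_ts < end)
        tags = det_tags[inside]
        times = det_ts[inside]
        if len(tags) == 0:
            bouts.append(Bout(states.nest_id, start, end, "unknown"))
            continue
        # split at change-overs: boundary = first detection of the new tag
        change = np.flatnonzero(tags[1:] != tags[:-1]) + 1
        bounds = [start] + [times[i] for i in change] + [end]
        seg_slices = np.split(np.arange(len(tags)), change)
        for k, idx in enumerate(seg_slices):
            b_start, b_end = bounds[k], bounds[k + 1]
            if b_end <= b_start:
                continue
            label = _label(tags[idx], times[idx])
            if bouts and bouts[-1].attending == label and bouts[-1].end == b_start:
                bouts[-1] = Bout(states.nest_id, bouts[-1].start, b_end, label)
            else:
                bouts.append(Bout(states.nest_id, b_start, b_end, label))
    return bouts


def apply_bout_labels(states: IncubationStateSeries, bouts: Sequence[Bout]) -> IncubationStateSeries:
    """Fill the per-reading ``attending`` column from segmented bouts."""
    df = states.df.copy()
    ts = pd.DatetimeIndex(df["timestamp_utc"])
    attending = np.where(df["incubated"].to_numpy(), "unknown", "none").astype(object)
    for b in bouts:
        mask = (ts >= b.start) & (ts < b.end) & df["incubated"].to_numpy()
        attending[mask] = b.attending
    df["attending"] = attending
    return IncubationStateSeries(states.nest_id, df)


def population_median_bout(bouts: Sequence[Bout]) -> float:
    """Sample median bout length in hours (midpoint convention for even n)."""
    if len(bouts) == 0:
        raise ValueError("cannot take the median of an empty bout list")
    return float(np.median([b.length_h for b in bouts]))


def estimate_incubation_start(
    meta: NestMetadata,
    ref: SpeciesReference,
    population_medians: Optional[Mapping] = None,
    flotation_lookup: Optional[Mapping[str, float]] = None,
) -> pd.Timestamp:
    """Estimate when incubation started, by precedence:

    1. a directly observed/actogram-supplied ``incubation_start``;
    2. laying rule: ``first_egg_date + (clutch_size - 1)`` days;
    3. ``hatch_start`` minus the species' typical incubation period;
    4. egg-flotation lookup: observation date minus looked-up elapsed days;
    5. the population(-year) median start of other nests.
    """
    if meta.incubation_start is not None:
        return meta.incubation_start
    if meta.first_egg_date is not None and meta.clutch_size is not None:
        return meta.first_egg_date + pd.Timedelta(days=meta.clutch_size - 1)
    if meta.hatch_start is not None:
        return meta.hatch_start - pd.Timedelta(days=ref.typical_incubation_period_d)
    if (
        meta.flotation_date is not None
        and meta.flotation_stage is not None
        and flotation_lookup is not None
        and meta.flotation_stage in flotation_lookup
    ):
        return meta.flotation_date - pd.Timedelta(days=float(flotation_lookup[meta.flotation_stage]))
    if population_medians is not None:
        for key in ((meta.population, meta.year), meta.population):
            if key in population_medians:
                return pd.Timestamp(population_medians[key])
    raise EstimationError(f"no incubation-start estimation pathway for nest {meta.nest_id}")
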