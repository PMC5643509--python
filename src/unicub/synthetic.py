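"""Synthetic nest-monitoring data with a ground-truth ledger.

Emulates the field recording setup: a nest/surface temperature probe pair
sampled at a fixed cadence plus RFID detections of the tagged parents.
Biparental nests alternate incubation bouts with log-normal lengths;
desertion makes one parent's bouts cease after its last departure, after
which the remaining parent incubates solo.  Uniparental profiles keep the
nest attended through the cold hours and take intermittent recesses during
the warm part of the day.  Nest temperature sits at the incubation
temperature while attended and relaxes exponentially toward the diel
ambient cycle while the nest is empty.

Every generated reading is backed by a :class:`TruthLedger` row so that
extraction and phase detection can be scored against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from unicub.data_model import Dataset, NestMetadata, RfidTrace, SpeciesReference, TemperatureTrace


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    Bout lengths are log-normal around ``median_bout_h`` (the population
    median is exactly the log-normal median), keeping lengths positive and
    right-skewed.  Cooling after departure is exponential relaxation toward
    ambient with time constant ``cooling_tau_min``.
    """

    n_nests: int = 10
    species: str = "sandpiper_sp"
    population: str = "tundra_site"
    latitude: float = 71.32
    longitude: float = -156.65
    typical_incubation_period_d: float = 20.0
    median_bout_h: float = 11.0
    bout_log_sd: float = 0.25
    exchange_gap_min: float = 3.0
    # circadian profile of uniparental attendance
    uniparental_species: bool = False
    uniparental_sex: str = "M"
    warm_start_h: float = 10.0
    warm_end_h: float = 18.0
    warm_attend_prob: float = 0.5
    night_attend_prob: float = 1.0
    recess_block_min: float = 30.0
    # desertion regime (biparental profiles only)
    desertion_prob: float = 0.0
    desertion_day_range: tuple[float, float] = (3.0, 10.0)
    desert_female_prob: float = 0.8
    solo_days_range: tuple[float, float] = (2.5, 6.0)
    solo_circadian: bool = False
    post_desertion_tail_h: float = 6.0
    capture_fraction: float = 0.0
    capture_lead_h: float = 6.0
    # thermal model
    ambient_mean_c: float = 5.0
    ambient_amplitude_c: float = 7.0
    ambient_coldest_hour: float = 2.0
    ambient_noise_sd: float = 0.0
    incubated_temp_c: float = 35.0
    nest_noise_sd: float = 0.0
    cooling_tau_min: float = 20.0
    # recording
    sampling_interval_s: float = 5.0
    rfid_every_n: int = 1
    rfid_detection_prob: float = 1.0
    start_date: str = "2015-06-01T00:00:00"
    chicks_found_delay_h: float = 6.0
    single_egg: bool = False
    clutch_size: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.n_nests <= 0:
            raise ConfigError(f"n_nests must be positive, got {self.n_nests}")
        for name in (
            "typical_incubation_period_d",
            "median_bout_h",
            "sampling_interval_s",
            "cooling_tau_min",
            "recess_block_min",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in (
            "desertion_prob",
            "desert_female_prob",
            "warm_attend_prob",
            "night_attend_prob",
            "capture_fraction",
            "rfid_detection_prob",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")

    def reference(self) -> SpeciesReference:
        flag = "biparental"
        if self.uniparental_species:
            flag = "uniparental-female" if self.uniparental_sex == "F" else "uniparental-male"
        return SpeciesReference(
            species=self.species,
            population=self.population,
            typical_incubation_period_d=self.typical_incubation_period_d,
            median_bout_h=self.median_bout_h,
            uniparental_flag=flag,
        )


@dataclass
class TruthLedger:
    """Ground truth for a simulated dataset.

    ``bouts`` holds every attended interval (one row per bout, tiling each
    nest's attended time without overlap); ``nests`` one row per nest with
    desertion/hatching truth.
    """

    bouts: pd.DataFrame
    nests: pd.DataFrame

    def nest_bouts(self, nest_id: str) -> pd.DataFrame:
        return self.bouts[self.bouts["nest_id"] == nest_id].reset_index(drop=True)

    def attending_at(self, nest_id: str, timestamps: Sequence[pd.Timestamp]) -> np.ndarray:
        """Truth attending parent ('F'/'M'/'none') at each timestamp."""
        ts = pd.DatetimeIndex(timestamps).asi8
        sub = self.nest_bouts(nest_id)
        out = np.full(len(ts), "none", dtype=object)
        starts = pd.DatetimeIndex(sub["start_utc"]).asi8
        ends = pd.DatetimeIndex(sub["end_utc"]).asi8
        sexes = sub["sex"].to_numpy()
        idx = np.searchsorted(starts, ts, side="right") - 1
        ok = (idx >= 0) & (ts < ends[np.clip(idx, 0, None)])
        out[ok] = sexes[idx[ok]]
        return out

    def validate(self) -> None:
        """Check that per-nest truth intervals do not overlap."""
        for nest_id, sub in self.bouts.groupby("nest_id"):
            sub = sub.sort_values("start_utc")
            if (sub["end_utc"].to_numpy()[:-1] > sub["start_utc"].to_numpy()[1:]).any():
                raise AssertionError(f"overlapping truth bouts for nest {nest_id}")


def ambient_temperature(
    hour_local: Union[float, np.ndarray],
    mean_c: float,
    amplitude_c: float,
    coldest_hour: float = 2.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Union[float, np.ndarray]:
    """Diel ambient temperature: 24-h sinusoid, coldest at ``coldest_hour``.

    With amplitude ``a`` the noise-free curve spans ``mean - a`` (at the
    coldest hour) to ``mean + a`` (12 h later).
    """
    h = np.asarray(hour_local, dtype=float)
    temp = mean_c - amplitude_c * np.cos(2.0 * np.pi * (h - coldest_hour) / 24.0)
    if noise_sd > 0.0:
        if rng is None:
            raise ConfigError("noise_sd > 0 requires an rng")
        temp = temp + rng.normal(0.0, noise_sd, size=temp.shape)
    if np.isscalar(hour_local):
        return float(temp)
    return temp


# ---------------------------------------------------------------------------
# schedules (in hours since incubation start, snapped to the sample grid)


def _snap(hours: float, dt_h: float) -> float:
    return round(hours / dt_h) * dt_h


def _circadian_intervals(
    rng: np.random.Generator,
    cfg: SimConfig,
    start_h: float,
    end_h: float,
    local_hour0: float,
) -> list[tuple[float, float]]:
    """Attended intervals for a circadian uniparental profile over [start, end)."""
    block_h = cfg.recess_block_min / 60.0
    attended = []
    t = start_h
    while t < end_h:
        b_end = min(t + block_h, end_h)
        hour = (local_hour0 + t) % 24.0
        if cfg.warm_start_h <= hour < cfg.warm_end_h:
            p = cfg.warm_attend_prob
        else:
            p = cfg.night_attend_prob
        if rng.random() < p:
            attended.append((t, b_end))
        t = b_end
    # merge adjacent blocks
    merged: list[tuple[float, float]] = []
    for s, e in attended:
        if merged and abs(merged[-1][1] - s) < 1e-9:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


@dataclass
class _NestTruth:
    nest_id: str
    bouts: list[tuple[float, float, str]]  # hours since t0
    deserted: bool = False
    desertion_h: Optional[float] = None
    deserting_sex: Optional[str] = None
    solo_start_h: Optional[float] = None
    solo_end_h: Optional[float] = None
    solo_sex: Optional[str] = None
    hatched: bool = False
    hatch_h: Optional[float] = None
    recording_end_h: float = 0.0
    events_h: list[tuple[float, str]] = field(default_factory=list)


def _biparental_truth(rng: np.random.Generator, cfg: SimConfig, nest_id: str, local_hour0: float) -> _NestTruth:
    dt_h = cfg.sampling_interval_s / 3600.0
    gap_h = cfg.exchange_gap_min / 60.0
    end_h = cfg.typical_incubation_period_d * 24.0

    bouts: list[tuple[float, float, str]] = []
    t = 0.0
    sex = "F" if rng.random() < 0.5 else "M"
    while t < end_h:
        length = cfg.median_bout_h * float(np.exp(cfg.bout_log_sd * rng.normal()))
        s, e = _snap(t, dt_h), _snap(min(t + length, end_h), dt_h)
        if e > s:
            bouts.append((s, e, sex))
        t = t + length + gap_h
        sex = "M" if sex == "F" else "F"

    truth = _NestTruth(nest_id=nest_id, bouts=bouts)
    deserts = rng.random() < cfg.desertion_prob
    desert_h = float(rng.uniform(*cfg.desertion_day_range)) * 24.0
    deserting_sex = "F" if rng.random() < cfg.desert_female_prob else "M"

    prior = [b for b in bouts if b[2] == deserting_sex and b[1] <= desert_h]
    if deserts and prior:
        desertion_h = prior[-1][1]  # deserter's last departure
        kept = [b for b in bouts if b[1] <= desertion_h]
        solo_sex = "M" if deserting_sex == "F" else "F"
        solo_start = _snap(desertion_h + gap_h, dt_h)
        solo_len = float(rng.uniform(*cfg.solo_days_range)) * 24.0
        solo_end = _snap(min(solo_start + solo_len, end_h), dt_h)
        hatched = solo_start + solo_len >= end_h
        if cfg.solo_circadian:
            solo_bouts = [
                (s, e, solo_sex)
                for s, e in _circadian_intervals(rng, cfg, solo_start, solo_end, local_hour0)
            ]
        else:
            solo_bouts = [(solo_start, solo_end, solo_sex)]
        truth.bouts = kept + solo_bouts
        truth.deserted = True
        truth.desertion_h = desertion_h
        truth.deserting_sex = deserting_sex
        truth.solo_start_h = solo_start
        truth.solo_end_h = solo_end
        truth.solo_sex = solo_sex
        truth.hatched = hatched
        truth.hatch_h = end_h if hatched else None
        truth.recording_end_h = (
            end_h + 2.0 if hatched else solo_end + cfg.post_desertion_tail_h
        )
        if rng.random() < cfg.capture_fraction:
            truth.events_h.append((max(desertion_h - cfg.capture_lead_h, 0.0), "capture"))
    else:
        truth.hatched = True
        truth.hatch_h = end_h
        truth.recording_end_h = end_h + 2.0
    return truth


def _uniparental_truth(rng: np.random.Generator, cfg: SimConfig, nest_id: str, local_hour0: float) -> _NestTruth:
    end_h = cfg.typical_incubation_period_d * 24.0
    sex = cfg.uniparental_sex
    bouts = [(s, e, sex) for s, e in _circadian_intervals(rng, cfg, 0.0, end_h, local_hour0)]
    return _NestTruth(
        nest_id=nest_id,
        bouts=bouts,
        hatched=True,
        hatch_h=end_h,
        recording_end_h=end_h + 2.0,
        solo_sex=sex,
    )


# ---------------------------------------------------------------------------
# sensor synthesis


def _nest_temperature(
    attended: np.ndarray,
    ambient: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Nest temperature: incubated while attended, exponential decay otherwise."""
    n = len(attended)
    dt_min = cfg.sampling_interval_s / 60.0
    temp = np.where(attended, cfg.incubated_temp_c, np.nan)
    # fill unattended runs with relaxation toward ambient
    i = 0
    while i < n:
        if not np.isnan(temp[i]):
            i += 1
            continue
        j = i
        while j < n and np.isnan(temp[j]):
            j += 1
        if i == 0:
            start_temp = ambient[0]
            base = ambient[0]
        else:
            start_temp = temp[i - 1]
            base = ambient[i - 1]
        elapsed = (np.arange(j - i) + 1) * dt_min
        temp[i:j] = ambient[i:j] + (start_temp - base) * np.exp(-elapsed / cfg.cooling_tau_min)
        i = j
    if cfg.nest_noise_sd > 0.0:
        temp = temp + rng.normal(0.0, cfg.nest_noise_sd, size=n)
    return temp


def _simulate_nest_arrays(
    cfg: SimConfig, rng: np.random.Generator, nest_id: str
) -> tuple[pd.DataFrame, pd.DataFrame, NestMetadata, _NestTruth]:
    t0 = pd.Timestamp(cfg.start_date)
    offset_h = cfg.longitude * 24.0 / 360.0
    local_hour0 = (t0.hour + t0.minute / 60.0 + t0.second / 3600.0 + offset_h) % 24.0

    if cfg.uniparental_species:
        truth = _uniparental_truth(rng, cfg, nest_id, local_hour0)
    else:
        truth = _biparental_truth(rng, cfg, nest_id, local_hour0)

    dt_h = cfg.sampling_interval_s / 3600.0
    n = int(round(truth.recording_end_h / dt_h)) + 1
    hours = np.arange(n) * dt_h
    times = t0 + pd.to_timedelta(np.round(hours * 3600.0).astype(np.int64), unit="s")

    sex_code = np.full(n, "none", dtype=object)
    for s, e, sex in truth.bouts:
        i0 = int(round(s / dt_h))
        i1 = int(round(e / dt_h))
        sex_code[i0:i1] = sex
    attended = sex_code != "none"

    hour_local = (local_hour0 + hours) % 24.0
    ambient = ambient_temperature(
        hour_local, cfg.ambient_mean_c, cfg.ambient_amplitude_c, cfg.ambient_coldest_hour
    )
    nest_temp = _nest_temperature(attended, ambient, cfg, rng)
    surface = ambient.copy()
    if cfg.ambient_noise_sd > 0.0:
        surface = surface + rng.normal(0.0, cfg.ambient_noise_sd, size=n)

    temp_rows = pd.DataFrame(
        {
            "timestamp_utc": times,
            "nest_temp_c": np.round(nest_temp, 4),
            "surface_temp_c": np.round(surface, 4),
        }
    )

    female_tag = f"{nest_id}-F"
    male_tag = f"{nest_id}-M"
    tag_of = {"F": female_tag, "M": male_tag}
    det_idx = np.flatnonzero(attended)
    if cfg.rfid_every_n > 1:
        det_idx = det_idx[det_idx % cfg.rfid_every_n == 0]
    if cfg.rfid_detection_prob < 1.0:
        det_idx = det_idx[rng.random(len(det_idx)) < cfg.rfid_detection_prob]
    rfid_rows = pd.DataFrame(
        {
            "timestamp_utc": times[det_idx],
            "tag_id": [tag_of[s] for s in sex_code[det_idx]],
        }
    )

    clutch = 1 if cfg.single_egg else cfg.clutch_size
    hatch_ts = t0 + pd.Timedelta(seconds=round(truth.hatch_h * 3600.0)) if truth.hatched else None
    outcome = "hatched" if truth.hatched else "deserted"
    meta = NestMetadata(
        nest_id=nest_id,
        species=cfg.species,
        population=cfg.population,
        latitude=cfg.latitude,
        longitude=cfg.longitude,
        clutch_size=clutch,
        first_egg_date=(t0 - pd.Timedelta(days=clutch - 1)).normalize(),
        hatch_start=hatch_ts,
        chicks_found=hatch_ts + pd.Timedelta(hours=cfg.chicks_found_delay_h)
        if hatch_ts is not None
        else None,
        incubation_start=t0,
        outcome=outcome,
        eggs_remaining=clutch,
        female_tag=female_tag if not (cfg.uniparental_species and cfg.uniparental_sex == "M") else None,
        male_tag=male_tag if not (cfg.uniparental_species and cfg.uniparental_sex == "F") else None,
        year=int(t0.year),
        events=[(t0 + pd.Timedelta(seconds=round(h * 3600.0)), kind) for h, kind in truth.events_h],
    )
    if cfg.uniparental_species:
        # the single tagged parent keeps its own tag
        if cfg.uniparental_sex == "M":
            meta.male_tag = male_tag
        else:
            meta.female_tag = female_tag
    return temp_rows, rfid_rows, meta, truth


def _td(hours: float) -> pd.Timedelta:
    """Hour offset as a whole-second Timedelta (avoids float-ns dust)."""
    return pd.Timedelta(seconds=round(hours * 3600.0))


def _truth_frames(t0: pd.Timestamp, truths: Sequence[_NestTruth]) -> TruthLedger:
    bout_rows = []
    nest_rows = []
    for tr in truths:
        for s, e, sex in sorted(tr.bouts):
            bout_rows.append(
                {
                    "nest_id": tr.nest_id,
                    "start_utc": t0 + _td(s),
                    "end_utc": t0 + _td(e),
                    "sex": sex,
                }
            )
        nest_rows.append(
            {
                "nest_id": tr.nest_id,
                "deserted": tr.deserted,
                "desertion_utc": t0 + _td(tr.desertion_h)
                if tr.desertion_h is not None
                else pd.NaT,
                "deserting_sex": tr.deserting_sex,
                "solo_sex": tr.solo_sex,
                "solo_start_utc": t0 + _td(tr.solo_start_h)
                if tr.solo_start_h is not None
                else pd.NaT,
                "solo_end_utc": t0 + _td(tr.solo_end_h)
                if tr.solo_end_h is not None
                else pd.NaT,
                "hatched": tr.hatched,
                "hatch_utc": t0 + _td(tr.hatch_h)
                if tr.hatch_h is not None
                else pd.NaT,
                "recording_end_utc": t0 + _td(tr.recording_end_h),
            }
        )
    ledger = TruthLedger(bouts=pd.DataFrame(bout_rows), nests=pd.DataFrame(nest_rows))
    ledger.validate()
    return ledger


def simulate_nest(
    config: SimConfig, seed: int, nest_id: str = "n000"
) -> tuple[TemperatureTrace, RfidTrace, NestMetadata, TruthLedger]:
    """Simulate a single nest; same contracts as :func:`generate_dataset`."""
    config.validate()
    rng = np.random.default_rng(seed)
    temp_rows, rfid_rows, meta, truth = _simulate_nest_arrays(config, rng, nest_id)
    ledger = _truth_frames(pd.Timestamp(config.start_date), [truth])
    return (
        TemperatureTrace(nest_id, temp_rows, sampling_interval_s=config.sampling_interval_s),
        RfidTrace(nest_id, rfid_rows),
        meta,
        ledger,
    )


def generate_dataset(
    config: SimConfig, seed: Optional[int] = None
) -> tuple[Dataset, TruthLedger]:
    """Generate a full synthetic dataset plus its truth ledger.

    Deterministic under a fixed seed (``config.seed`` unless overridden).
    """
    config.validate()
    seed = config.seed if seed is None else seed
    children = np.random.SeedSequence(seed).spawn(config.n_nests)

    ds = Dataset()
    ref = config.reference()
    ds.references[(ref.species, ref.population)] = ref
    truths = []
    for i, child in enumerate(children):
        nest_id = f"n{i:03d}"
        rng = np.random.default_rng(child)
        temp_rows, rfid_rows, meta, truth = _simulate_nest_arrays(config, rng, nest_id)
        ds.temperature[nest_id] = TemperatureTrace(
            nest_id, temp_rows, sampling_interval_s=config.sampling_interval_s
        )
        ds.rfid[nest_id] = RfidTrace(nest_id, rfid_rows)
        ds.metadata[nest_id] = meta
        truths.append(truth)
    ledger = _truth_frames(pd.Timestamp(config.start_date), truths)
    return ds, ledger
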