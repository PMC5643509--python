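"""Core domain types shared across the pipeline.

Bulk tabular payloads (sensor readings, detections) are pandas DataFrames
with fixed column schemas; thin dataclasses carry identity, validation
state and the scalar metadata alongside them.  Timestamps are tz-naive and
denote UTC unless a column is explicitly suffixed ``_local``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Column schema of a temperature log.
TEMPERATURE_COLUMNS = ("timestamp_utc", "nest_temp_c", "surface_temp_c")
#: Column schema of an RFID detection log.
RFID_COLUMNS = ("timestamp_utc", "tag_id")

OUTCOMES = ("hatched", "depredated", "deserted", "unknown")
EVENT_KINDS = ("capture", "removal")
SEXES = ("F", "M")

#: Incubation-type labels used by attendance records and models.
TYPE_BIPARENTAL = "biparental"
TYPE_UNI_BI = "uniparental_biparental_species"
TYPE_UNI_UNI = "uniparental_uniparental_species"
INCUBATION_TYPES = (TYPE_BIPARENTAL, TYPE_UNI_BI, TYPE_UNI_UNI)

#: Uniparental-phase cause labels.
CAUSE_NATURAL = "natural/unknown"
CAUSE_CAPTURE = "post-capture"
CAUSE_REMOVAL = "experimental-removal"
CAUSE_TEMPORAL = "temporal"
CAUSES = (CAUSE_NATURAL, CAUSE_CAPTURE, CAUSE_REMOVAL, CAUSE_TEMPORAL)


class ValidationError(ValueError):
    """Raised when input rows violate the data-model invariants.

    Carries a list of ``(source, row, message)`` problems so that every
    offending row is located; loading is all-or-nothing.
    """

    def __init__(self, problems: Sequence[tuple[str, object, str]]):
        self.problems = list(problems)
        lines = [f"{src} [row {row}]: {msg}" for src, row, msg in self.problems]
        super().__init__("validation failed:\n" + "\n".join(lines))


class UnusableTraceError(ValueError):
    """Raised when a trace contains no usable sensor readings."""


def _require_columns(df: pd.DataFrame, columns: Iterable[str], source: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError([(source, "-", f"missing columns {missing}")])


@dataclass
class TemperatureTrace:
    """Per-nest nest/surface temperature stream at a nominal fixed cadence."""

    nest_id: str
    rows: pd.DataFrame
    sampling_interval_s: float = 5.0
    usable: bool = True

    def __post_init__(self) -> None:
        _require_columns(self.rows, TEMPERATURE_COLUMNS, f"temperature:{self.nest_id}")
        self.rows = self.rows.reset_index(drop=True)
        if len(self.rows) == 0:
            self.usable = False

    def validate(self) -> list[tuple[str, object, str]]:
        problems: list[tuple[str, object, str]] = []
        src = f"temperature:{self.nest_id}"
        ts = self.rows["timestamp_utc"]
        if len(ts) > 1:
            bad = np.flatnonzero(np.diff(ts.to_numpy()) <= np.timedelta64(0, "s"))
            problems.extend(
                (src, int(i) + 1, "timestamps not strictly increasing") for i in bad
            )
        for col in ("nest_temp_c", "surface_temp_c"):
            vals = self.rows[col].to_numpy(dtype=float)
            inf = np.flatnonzero(np.isinf(vals))
            problems.extend((src, int(i), f"non-finite {col}") for i in inf)
        return problems

    @property
    def span(self) -> Optional[tuple[pd.Timestamp, pd.Timestamp]]:
        if len(self.rows) == 0:
            return None
        return self.rows["timestamp_utc"].iloc[0], self.rows["timestamp_utc"].iloc[-1]


@dataclass
class RfidTrace:
    """Per-nest RFID tag-detection stream."""

    nest_id: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.rows, RFID_COLUMNS, f"rfid:{self.nest_id}")
        self.rows = self.rows.reset_index(drop=True)

    def validate(self) -> list[tuple[str, object, str]]:
        problems = []
        src = f"rfid:{self.nest_id}"
        ts = self.rows["timestamp_utc"]
        if len(ts) > 1:
            bad = np.flatnonzero(np.diff(ts.to_numpy()) < np.timedelta64(0, "s"))
            problems.extend((src, int(i) + 1, "timestamps decrease") for i in bad)
        return problems


@dataclass
class NestMetadata:
    """Identity, reference dates, events and outcome for one nest."""

    nest_id: str
    species: str
    population: str
    latitude: float
    longitude: float
    clutch_size: Optional[int] = None
    first_egg_date: Optional[pd.Timestamp] = None
    hatch_start: Optional[pd.Timestamp] = None
    chicks_found: Optional[pd.Timestamp] = None
    flotation_date: Optional[pd.Timestamp] = None
    flotation_stage: Optional[str] = None
    incubation_start: Optional[pd.Timestamp] = None
    outcome: str = "unknown"
    eggs_remaining: Optional[int] = None
    female_tag: Optional[str] = None
    male_tag: Optional[str] = None
    year: Optional[int] = None
    events: list[tuple[pd.Timestamp, str]] = field(default_factory=list)
    #: intervals with unusable sensor data (e.g. dislocated probe), dropped
    #: before attendance windows are formed
    excluded_spans: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)

    def validate(self) -> list[tuple[str, object, str]]:
        problems = []
        src = f"metadata:{self.nest_id}"
        if not -90.0 <= self.latitude <= 90.0:
            problems.append((src, "-", f"latitude {self.latitude} out of [-90, 90]"))
        if not -180.0 <= self.longitude <= 180.0:
            problems.append((src, "-", f"longitude {self.longitude} out of [-180, 180]"))
        if self.outcome not in OUTCOMES:
            problems.append((src, "-", f"unknown outcome {self.outcome!r}"))
        if (
            self.hatch_start is not None
            and self.chicks_found is not None
            and self.hatch_start > self.chicks_found
        ):
            problems.append((src, "-", "hatch_start after chicks_found"))
        for ts, kind in self.events:
            if kind not in EVENT_KINDS:
                problems.append((src, "-", f"unknown event kind {kind!r}"))
        return problems

    def tag_sex(self, tag_id: str) -> str:
        if self.female_tag is not None and tag_id == self.female_tag:
            return "F"
        if self.male_tag is not None and tag_id == self.male_tag:
            return "M"
        return "unknown"

    @property
    def tag_map(self) -> dict[str, str]:
        out = {}
        if self.female_tag:
            out[self.female_tag] = "F"
        if self.male_tag:
            out[self.male_tag] = "M"
        return out


@dataclass
class SpeciesReference:
    """Species/population reference values used throughout the pipeline."""

    species: str
    population: str
    typical_incubation_period_d: float
    median_bout_h: float
    uniparental_flag: str = "biparental"  # biparental | uniparental-female | uniparental-male

    def validate(self) -> list[tuple[str, object, str]]:
        problems = []
        src = f"species:{self.species}/{self.population}"
        if not self.typical_incubation_period_d > 0:
            problems.append((src, "-", "typical_incubation_period_d must be > 0"))
        if not self.median_bout_h > 0:
            problems.append((src, "-", "median_bout_h must be > 0"))
        return problems


@dataclass
class Dataset:
    """All traces, metadata and references of one study, keyed by nest."""

    temperature: dict[str, TemperatureTrace] = field(default_factory=dict)
    rfid: dict[str, RfidTrace] = field(default_factory=dict)
    metadata: dict[str, NestMetadata] = field(default_factory=dict)
    references: dict[tuple[str, str], SpeciesReference] = field(default_factory=dict)

    @property
    def nest_ids(self) -> list[str]:
        return sorted(self.metadata)

    def reference_for(self, nest_id: str) -> SpeciesReference:
        meta = self.metadata[nest_id]
        key = (meta.species, meta.population)
        if key in self.references:
            return self.references[key]
        # fall back to a species-level entry if the population is not listed
        for (sp, _pop), ref in self.references.items():
            if sp == meta.species:
                return ref
        raise KeyError(f"no species reference for nest {nest_id} ({key})")

    def validate(self) -> None:
        """Cross-check invariants; raise :class:`ValidationError` on failure."""
        problems: list[tuple[str, object, str]] = []
        for trace in self.temperature.values():
            problems.extend(trace.validate())
            if trace.nest_id not in self.metadata:
                problems.append(
                    ("dataset", trace.nest_id, "temperature trace without metadata")
                )
        for trace in self.rfid.values():
            problems.extend(trace.validate())
            if trace.nest_id not in self.metadata:
                problems.append(("dataset", trace.nest_id, "rfid trace without metadata"))
        species_known = {sp for sp, _ in self.references}
        for meta in self.metadata.values():
            problems.extend(meta.validate())
            if meta.species not in species_known:
                problems.append(
                    ("dataset", meta.nest_id, f"unknown species code {meta.species!r}")
                )
        for ref in self.references.values():
            problems.extend(ref.validate())
        if problems:
            raise ValidationError(problems)


@dataclass
class Bout:
    """A maximal continuous incubation session by one parent."""

    nest_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    attending: str = "unknown"  # F | M | unknown

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"bout end {self.end} not after start {self.start}")

    @property
    def length_h(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)


@dataclass
class UniparentalPhase:
    """A qualified solo-incubation interval.

    ``onset`` is the start of the underlying solo span (the partner's final
    departure); ``start`` excludes the remaining parent's first regular bout.
    """

    nest_id: str
    sex: str
    start: pd.Timestamp
    end: pd.Timestamp
    onset: Optional[pd.Timestamp] = None
    cause: Optional[str] = None
    censored: bool = False
    censored_start: bool = False
    start_fraction_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"phase end {self.end} not after start {self.start}")

    @property
    def duration_d(self) -> float:
        return (self.end - self.start) / pd.Timedelta(days=1)


def bouts_to_frame(bouts: Sequence[Bout]) -> pd.DataFrame:
    """Tabular view of a bout list (one row per bout)."""
    return pd.DataFrame(
        {
            "nest_id": [b.nest_id for b in bouts],
            "start_utc": [b.start for b in bouts],
            "end_utc": [b.end for b in bouts],
            "attending": [b.attending for b in bouts],
            "length_h": [b.length_h for b in bouts],
        }
    )


def phases_to_frame(phases: Sequence[UniparentalPhase]) -> pd.DataFrame:
    """Tabular view of a phase list (one row per phase)."""
    return pd.DataFrame(
        {
            "nest_id": [p.nest_id for p in phases],
            "sex": [p.sex for p in phases],
            "start_utc": [p.start for p in phases],
            "end_utc": [p.end for p in phases],
            "onset_utc": [p.onset for p in phases],
            "duration_d": [p.duration_d for p in phases],
            "start_fraction_pct": [p.start_fraction_pct for p in phases],
            "cause": [p.cause for p in phases],
            "censored": [p.censored for p in phases],
            "censored_start": [p.censored_start for p in phases],
        }
    )
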