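"""Reading and writing the pipeline's CSV interchange files.

All files are plain CSV with ISO-8601 UTC timestamps.  A dataset directory
holds::

    temperature.csv  nest_id,timestamp_utc,nest_temp_c,surface_temp_c
    rfid.csv         nest_id,timestamp_utc,tag_id
    nests.csv        one row per nest (see NEST_COLUMNS)
    species.csv      species,population,typical_incubation_period_d,
                     median_bout_h,uniparental_flag
    events.csv       nest_id,timestamp_utc,kind          (optional)

Loading is all-or-nothing: rows violating invariants produce a
:class:`~unicub.data_model.ValidationError` naming file and row; nothing is
silently dropped.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from unicub.data_model import (
    Dataset,
    NestMetadata,
    RfidTrace,
    SpeciesReference,
    TemperatureTrace,
    ValidationError,
)

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"

NEST_COLUMNS = (
    "nest_id",
    "species",
    "population",
    "latitude",
    "longitude",
    "clutch_size",
    "first_egg_date",
    "hatch_start",
    "chicks_found",
    "flotation_date",
    "flotation_stage",
    "incubation_start",
    "outcome",
    "eggs_remaining",
    "female_tag",
    "male_tag",
    "year",
)

SPECIES_COLUMNS = (
    "species",
    "population",
    "typical_incubation_period_d",
    "median_bout_h",
    "uniparental_flag",
)

#: column-name suffixes parsed as datetimes on read
_DATETIME_SUFFIXES = ("_utc", "_local", "_date", "_start", "_found", "_time", "_end")


def _is_datetime_column(name: str) -> bool:
    return name.endswith(_DATETIME_SUFFIXES) or name in ("hatch_start", "chicks_found")


def _parse_timestamp(value) -> Optional[pd.Timestamp]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    ts = pd.Timestamp(value)
    return None if pd.isna(ts) else ts


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read an interchange CSV, parsing timestamp-like columns by suffix."""
    df = pd.read_csv(path)
    for col in df.columns:
        if _is_datetime_column(col):
            df[col] = pd.to_datetime(df[col], format="ISO8601")
    return df


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write an interchange CSV with ISO-8601 timestamps; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime(TIMESTAMP_FORMAT)
    out.to_csv(path, index=False)
    return path


def write_outputs(tables: Mapping[str, pd.DataFrame], outdir: Union[str, Path]) -> dict[str, Path]:
    """Write every pipeline product table as ``<name>.csv`` under ``outdir``.

    Round-trip stable: :func:`read_table` on a written file reproduces the
    table field-for-field (timestamps at second resolution).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        paths[name] = write_table(df, outdir / f"{name}.csv")
    return paths


def _split_by_nest(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    out = {}
    for nest_id, sub in df.groupby("nest_id", sort=True):
        out[str(nest_id)] = sub.drop(columns=["nest_id"]).reset_index(drop=True)
    return out


def _metadata_from_row(row: pd.Series, events: list[tuple[pd.Timestamp, str]]) -> NestMetadata:
    def opt_int(v):
        return None if pd.isna(v) else int(v)

    return NestMetadata(
        nest_id=str(row["nest_id"]),
        species=str(row["species"]),
        population=str(row["population"]),
        latitude=float(row["latitude"]),
        longitude=float(row["longitude"]),
        clutch_size=opt_int(row.get("clutch_size")),
        first_egg_date=_parse_timestamp(row.get("first_egg_date")),
        hatch_start=_parse_timestamp(row.get("hatch_start")),
        chicks_found=_parse_timestamp(row.get("chicks_found")),
        flotation_date=_parse_timestamp(row.get("flotation_date")),
        flotation_stage=None if pd.isna(row.get("flotation_stage")) else str(row["flotation_stage"]),
        incubation_start=_parse_timestamp(row.get("incubation_start")),
        outcome=str(row.get("outcome", "unknown")),
        eggs_remaining=opt_int(row.get("eggs_remaining")),
        female_tag=None if pd.isna(row.get("female_tag")) else str(row["female_tag"]),
        male_tag=None if pd.isna(row.get("male_tag")) else str(row["male_tag"]),
        year=opt_int(row.get("year")),
        events=events,
    )


def load_dataset(
    directory: Union[str, Path],
    config: Optional[Mapping] = None,
) -> Dataset:
    """Load and validate a dataset directory into a :class:`Dataset`.

    Parameters
    ----------
    directory:
        Directory containing the interchange CSVs described in the module
        docstring.  ``events.csv`` is optional.
    config:
        Optional key/value configuration; honours ``sampling_interval_s``
        (nominal temperature cadence, default 5).
    """
    directory = Path(directory)
    config = dict(config or {})
    interval = float(config.get("sampling_interval_s", 5.0))

    for required in ("temperature.csv", "rfid.csv", "nests.csv", "species.csv"):
        if not (directory / required).exists():
            raise FileNotFoundError(directory / required)

    temp = read_table(directory / "temperature.csv")
    rfid = read_table(directory / "rfid.csv")
    nests = read_table(directory / "nests.csv")
    species = read_table(directory / "species.csv")
    events_path = directory / "events.csv"
    events = read_table(events_path) if events_path.exists() else pd.DataFrame(
        columns=["nest_id", "timestamp_utc", "kind"]
    )

    ds = Dataset()
    for _, row in species.iterrows():
        ref = SpeciesReference(
            species=str(row["species"]),
            population=str(row["population"]),
            typical_incubation_period_d=float(row["typical_incubation_period_d"]),
            median_bout_h=float(row["median_bout_h"]),
            uniparental_flag=str(row.get("uniparental_flag", "biparental")),
        )
        ds.references[(ref.species, ref.population)] = ref

    events_by_nest: dict[str, list[tuple[pd.Timestamp, str]]] = {}
    for _, row in events.iterrows():
        events_by_nest.setdefault(str(row["nest_id"]), []).append(
            (pd.Timestamp(row["timestamp_utc"]), str(row["kind"]))
        )

    for _, row in nests.iterrows():
        meta = _metadata_from_row(row, events_by_nest.get(str(row["nest_id"]), []))
        ds.metadata[meta.nest_id] = meta

    for nest_id, sub in _split_by_nest(temp).items():
        ds.temperature[nest_id] = TemperatureTrace(nest_id, sub, sampling_interval_s=interval)
    for nest_id, sub in _split_by_nest(rfid).items():
        ds.rfid[nest_id] = RfidTrace(nest_id, sub)

    # nests listed in metadata but absent from the temperature file get an
    # explicit empty (unusable) trace rather than disappearing
    empty = pd.DataFrame(columns=list(TemperatureTrace.__annotations__) and
                         ["timestamp_utc", "nest_temp_c", "surface_temp_c"])
    for nest_id in ds.metadata:
        if nest_id not in ds.temperature:
            ds.temperature[nest_id] = TemperatureTrace(
                nest_id, empty.copy(), sampling_interval_s=interval
            )
        if nest_id not in ds.rfid:
            ds.rfid[nest_id] = RfidTrace(
                nest_id, pd.DataFrame(columns=["timestamp_utc", "tag_id"])
            )

    ds.validate()
    return ds


def write_dataset(ds: Dataset, outdir: Union[str, Path]) -> dict[str, Path]:
    """Write a :class:`Dataset` back into the interchange CSV layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    temp_frames = []
    for nest_id in sorted(ds.temperature):
        sub = ds.temperature[nest_id].rows.copy()
        sub.insert(0, "nest_id", nest_id)
        temp_frames.append(sub)
    rfid_frames = []
    for nest_id in sorted(ds.rfid):
        sub = ds.rfid[nest_id].rows.copy()
        sub.insert(0, "nest_id", nest_id)
        rfid_frames.append(sub)

    nest_rows = []
    event_rows = []
    for nest_id in ds.nest_ids:
        m = ds.metadata[nest_id]
        nest_rows.append(
            {
                "nest_id": m.nest_id,
                "species": m.species,
                "population": m.population,
                "latitude": m.latitude,
                "longitude": m.longitude,
                "clutch_size": m.clutch_size,
                "first_egg_date": m.first_egg_date,
                "hatch_start": m.hatch_start,
                "chicks_found": m.chicks_found,
                "flotation_date": m.flotation_date,
                "flotation_stage": m.flotation_stage,
                "incubation_start": m.incubation_start,
                "outcome": m.outcome,
                "eggs_remaining": m.eggs_remaining,
                "female_tag": m.female_tag,
                "male_tag": m.male_tag,
                "year": m.year,
            }
        )
        for ts, kind in m.events:
            event_rows.append({"nest_id": m.nest_id, "timestamp_utc": ts, "kind": kind})

    species_rows = [
        {
            "species": r.species,
            "population": r.population,
            "typical_incubation_period_d": r.typical_incubation_period_d,
            "median_bout_h": r.median_bout_h,
            "uniparental_flag": r.uniparental_flag,
        }
        for r in ds.references.values()
    ]

    tables = {
        "temperature": pd.concat(temp_frames, ignore_index=True)
        if temp_frames
        else pd.DataFrame(columns=["nest_id", "timestamp_utc", "nest_temp_c", "surface_temp_c"]),
        "rfid": pd.concat(rfid_frames, ignore_index=True)
        if rfid_frames
        else pd.DataFrame(columns=["nest_id", "timestamp_utc", "tag_id"]),
        "nests": pd.DataFrame(nest_rows, columns=list(NEST_COLUMNS)),
        "species": pd.DataFrame(species_rows, columns=list(SPECIES_COLUMNS)),
    }
    if event_rows:
        tables["events"] = pd.DataFrame(event_rows)
    return write_outputs(tables, outdir)
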