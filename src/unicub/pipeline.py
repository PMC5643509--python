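"""End-to-end orchestration: dataset -> states -> bouts -> phases ->
attendance -> summary tables.

Used by the CLI and by the determinism checks; every stage returns plain
DataFrames so the whole product set can be written with
:func:`unicub.io.write_outputs`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from unicub.attendance import AttendanceParams, daily_attendance, hourly_attendance
from unicub.data_model import Dataset, bouts_to_frame, phases_to_frame
from unicub.extraction import (
    ExtractionParams,
    apply_bout_labels,
    classify_incubation,
    estimate_incubation_start,
    population_median_bout,
    segment_bouts,
)
from unicub.phases import PhaseParams, detect_uniparental_phases, phase_metrics
from unicub.reporting import case_summary_stats, species_summary_table
log = logging.getLogger("unicub")


@dataclass
class PipelineResult:
    states: dict = field(default_factory=dict)
    bouts: dict = field(default_factory=dict)
    phases: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_pipeline(
    ds: Dataset,
    extraction_params: Optional[ExtractionParams] = None,
    phase_params: Optional[PhaseParams] = None,
    attendance_params: Optional[AttendanceParams] = None,
    total_monitored: Optional[int] = None,
) -> PipelineResult:
    """Run extraction, phase detection, attendance and summaries on ``ds``."""
    xp = extraction_params or ExtractionParams()
    pp = phase_params or PhaseParams()
    ap = attendance_params or AttendanceParams()
    res = PipelineResult()

    # extraction
    bout_frames = []
    for nest_id in ds.nest_ids:
        trace = ds.temperature[nest_id]
        if not trace.usable or len(trace.rows) == 0:
            continue
        meta = ds.metadata[nest_id]
        states = classify_incubation(trace, xp, longitude=meta.longitude)
        bouts = segment_bouts(states, ds.rfid.get(nest_id), xp, tag_sex=meta.tag_map)
        states = apply_bout_labels(states, bouts)
        res.states[nest_id] = states
        res.bouts[nest_id] = bouts
        if bouts:
            bout_frames.append(bouts_to_frame(bouts))
    log.info("extraction: %d nests with bouts", len(res.bouts))

    # population median bouts (biparental species only feed the phase rule)
    pop_bouts: dict[tuple[str, str], list] = {}
    for nest_id, bouts in res.bouts.items():
        meta = ds.metadata[nest_id]
        pop_bouts.setdefault((meta.species, meta.population), []).extend(bouts)

    # phase detection on biparental-species nests
    phase_frames = []
    for nest_id, bouts in res.bouts.items():
        meta = ds.metadata[nest_id]
        ref = ds.reference_for(nest_id)
        if ref.uniparental_flag != "biparental":
            res.phases[nest_id] = []
            continue
        median_h = ref.median_bout_h
        recording_end = ds.temperature[nest_id].rows["timestamp_utc"].iloc[-1]
        phases = detect_uniparental_phases(
            bouts, median_h, meta, pp, recording_end=recording_end
        )
        start = meta.incubation_start or estimate_incubation_start(meta, ref)
        for p in phases:
            phase_metrics(p, start, ref)
        res.phases[nest_id] = phases
        if phases:
            phase_frames.append(phases_to_frame(phases))
    n_phases = sum(len(v) for v in res.phases.values())
    log.info("phase detection: %d phases", n_phases)

    # attendance
    daily_frames, hourly_frames = [], []
    for nest_id, states in res.states.items():
        meta = ds.metadata[nest_id]
        ref = ds.reference_for(nest_id)
        phases = res.phases.get(nest_id, [])
        d = daily_attendance(states, phases, meta, ref, ap)
        h = hourly_attendance(states, phases, meta, ref, ap)
        for frame in (d, h):
            frame["species"] = meta.species
            frame["sex"] = phases[0].sex if phases else None
        daily_frames.append(d)
        hourly_frames.append(h)

    res.tables["bouts"] = (
        pd.concat(bout_frames, ignore_index=True) if bout_frames else bouts_to_frame([])
    )
    res.tables["phases"] = (
        pd.concat(phase_frames, ignore_index=True) if phase_frames else phases_to_frame([])
    )
    res.tables["daily_attendance"] = (
        pd.concat(daily_frames, ignore_index=True) if daily_frames else pd.DataFrame()
    )
    res.tables["hourly_attendance"] = (
        pd.concat(hourly_frames, ignore_index=True) if hourly_frames else pd.DataFrame()
    )

    # summaries
    nest_rows = []
    for nest_id in ds.nest_ids:
        meta = ds.metadata[nest_id]
        nest_rows.append(
            {
                "nest_id": nest_id,
                "species": meta.species,
                "population": meta.population,
                "outcome": meta.outcome,
                "uniparental": bool(res.phases.get(nest_id)),
                "sex": res.phases[nest_id][0].sex if res.phases.get(nest_id) else None,
            }
        )
    nests_df = pd.DataFrame(nest_rows)
    res.tables["species_summary"] = species_summary_table(
        nests_df, total_monitored=total_monitored
    )
    cases = res.tables["phases"].rename(columns={"start_fraction_pct": "start_fraction_pct"})
    stats = case_summary_stats(cases) if len(cases) else {"n_cases": 0, "empty": True}
    res.tables["case_stats"] = pd.json_normalize(stats, sep="_")
    log.info("attendance: %d daily, %d hourly records",
             len(res.tables["daily_attendance"]), len(res.tables["hourly_attendance"]))
    return res
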