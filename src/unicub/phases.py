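"""Detection and description of qualified uniparental incubation phases.

A solo span is a maximal run of consecutive bouts by the same parent.  The
parent's first regular bout (one population median bout from the span
onset) is excluded; the remainder qualifies as a uniparental phase iff it
is at least ``qualify_multiple`` (default 2) population median bouts long.
Phase ends are trimmed 6 h before the start of hatching or 24 h before the
chicks were found, whichever applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from unicub.data_model import (
    Bout,
    CAUSE_CAPTURE,
    CAUSE_NATURAL,
    CAUSE_REMOVAL,
    CAUSE_TEMPORAL,
    NestMetadata,
    SpeciesReference,
    UniparentalPhase,
)


@dataclass
class PhaseParams:
    """Knobs of the uniparental-phase definition."""

    #: required phase length after removing the first regular bout, in
    #: population median bouts (2.0 means total solo time >= 3 medians)
    qualify_multiple: float = 2.0
    #: window before the solo onset within which a capture event attributes
    #: the phase to capture/release
    capture_window_h: float = 24.0
    hatch_trim_h: float = 6.0
    chicks_trim_h: float = 24.0


def _trim_end(
    end: pd.Timestamp, meta: NestMetadata, params: PhaseParams
) -> pd.Timestamp:
    trimmed = end
    if meta.hatch_start is not None:
        trimmed = min(trimmed, meta.hatch_start - pd.Timedelta(hours=params.hatch_trim_h))
    if meta.chicks_found is not None:
        trimmed = min(trimmed, meta.chicks_found - pd.Timedelta(hours=params.chicks_trim_h))
    return trimmed


def detect_uniparental_phases(
    bouts: Sequence[Bout],
    median_bout_h: float,
    meta: NestMetadata,
    params: Optional[PhaseParams] = None,
    recording_end: Optional[pd.Timestamp] = None,
) -> list[UniparentalPhase]:
    """Find qualified uniparental phases in a nest's bout sequence.

    Multiple phases per nest are possible (temporal desertion followed by a
    biparental period and a later permanent desertion).  ``censored`` marks
    phases that were still running when the recording ended;
    ``censored_start`` marks phases whose solo span opens the recording, so
    the partner's departure was never observed.
    """
    params = params or PhaseParams()
    if median_bout_h <= 0:
        raise ValueError(f"median_bout_h must be positive, got {median_bout_h}")
    if not bouts:
        return []

    ordered = sorted(bouts, key=lambda b: b.start)
    median = pd.Timedelta(hours=median_bout_h)

    # group consecutive bouts by attending label
    runs: list[list[Bout]] = [[ordered[0]]]
    for b in ordered[1:]:
        if b.attending == runs[-1][-1].attending:
            runs[-1].append(b)
        else:
            runs.append([b])

    phases: list[UniparentalPhase] = []
    for k, run in enumerate(runs):
        onset = run[0].start
        span_end = _trim_end(run[-1].end, meta, params)
        phase_start = onset + median
        if span_end - phase_start < params.qualify_multiple * median:
            continue
        censored = (
            recording_end is not None
            and run[-1].end >= recording_end
            and span_end == run[-1].end
        )
        phases.append(
            UniparentalPhase(
                nest_id=meta.nest_id,
                sex=run[0].attending,
                start=phase_start,
                end=span_end,
                onset=onset,
                censored=bool(censored),
                censored_start=(k == 0),
            )
        )
    for p in phases:
        p.cause = classify_cause(p, meta, ordered, params)
    return phases


def phase_metrics(
    phase: UniparentalPhase,
    incubation_start: pd.Timestamp,
    ref: SpeciesReference,
) -> tuple[float, float]:
    """Start fraction (% of the typical incubation period elapsed at phase
    start; values > 100 allowed) and duration in days.

    A phase starting before the incubation start yields a negative fraction,
    flagged as a data anomaly via a warning.
    """
    period = pd.Timedelta(days=ref.typical_incubation_period_d)
    fraction = 100.0 * (phase.start - incubation_start) / period
    if fraction < 0:
        warnings.warn(
            f"phase of nest {phase.nest_id} starts before incubation start "
            f"(fraction {fraction:.1f}%); data anomaly",
            stacklevel=2,
        )
    phase.start_fraction_pct = float(fraction)
    return float(fraction), phase.duration_d


def classify_cause(
    phase: UniparentalPhase,
    meta: NestMetadata,
    bouts: Sequence[Bout],
    params: Optional[PhaseParams] = None,
) -> str:
    """Attribute a phase to removal, capture, temporal desertion or nature.

    Priority: experimental removal before the solo onset beats a capture
    within the attribution window, which beats a later return to biparental
    incubation ('temporal'); anything else is natural/unknown.
    """
    params = params or PhaseParams()
    onset = phase.onset if phase.onset is not None else phase.start
    window = pd.Timedelta(hours=params.capture_window_h)
    for ts, kind in meta.events:
        if kind == "removal" and ts <= onset:
            return CAUSE_REMOVAL
    for ts, kind in meta.events:
        if kind == "capture" and onset - window <= ts <= onset:
            return CAUSE_CAPTURE
    for b in bouts:
        if b.start >= phase.end and b.attending not in (phase.sex, "unknown"):
            return CAUSE_TEMPORAL
    return CAUSE_NATURAL
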