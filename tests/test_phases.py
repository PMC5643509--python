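import numpy as np
import pandas as pd
import pytest

from unicub.data_model import (
    Bout,
    CAUSE_CAPTURE,
    CAUSE_NATURAL,
    CAUSE_REMOVAL,
    CAUSE_TEMPORAL,
    NestMetadata,
    SpeciesReference,
)
from unicub.extraction import ExtractionParams, classify_incubation, segment_bouts
from unicub.phases import PhaseParams, classify_cause, detect_uniparental_phases, phase_metrics
from unicub.synthetic import SimConfig, generate_dataset

T0 = pd.Timestamp("2015-06-01 00:00:00")
REF = SpeciesReference("sp", "pop", 20.0, 10.0)


def _meta(**kw):
    return NestMetadata("n", "sp", "pop", 71.0, -156.0, **kw)


def _bout(start_h, end_h, sex):
    return Bout("n", T0 + pd.Timedelta(hours=start_h), T0 + pd.Timedelta(hours=end_h), sex)


def _alternation(until_h, bout_h=10.0):
    bouts, t, sex = [], 0.0, "F"
    while t < until_h:
        bouts.append(_bout(t, min(t + bout_h, until_h), sex))
        t += bout_h
        sex = "M" if sex == "F" else "F"
    return bouts


class TestDetectionRule:
    def test_solo_span_40h_yields_30h_phase(self):
        # median 10 h: first regular bout excluded, remainder 30 h >= 20 h
        bouts = [_bout(0, 10, "F"), _bout(10, 20, "M"), _bout(20, 60, "F")]
        phases = detect_uniparental_phases(bouts, 10.0, _meta())
        assert len(phases) == 1
        p = phases[0]
        assert p.sex == "F"
        assert p.onset == T0 + pd.Timedelta(hours=20)
        assert p.start == T0 + pd.Timedelta(hours=30)
        assert p.end == T0 + pd.Timedelta(hours=60)
        assert p.duration_d == pytest.approx(30 / 24)

    def test_solo_span_25h_does_not_qualify(self):
        bouts = [_bout(0, 10, "F"), _bout(10, 20, "M"), _bout(20, 45, "F")]
        assert detect_uniparental_phases(bouts, 10.0, _meta()) == []

    def test_normal_alternation_yields_no_phase(self):
        assert detect_uniparental_phases(_alternation(200.0), 10.0, _meta()) == []

    def test_nonpositive_median_raises(self):
        with pytest.raises(ValueError):
            detect_uniparental_phases([_bout(0, 10, "F")], 0.0, _meta())

    def test_empty_bouts(self):
        assert detect_uniparental_phases([], 10.0, _meta()) == []

    def test_solo_run_of_multiple_bouts_counts_as_one_span(self):
        # solo parent with brief recesses: consecutive same-sex bouts
        bouts = [_bout(0, 10, "M"), _bout(10, 20, "F"), _bout(20, 40, "F"),
                 _bout(41, 70, "F")]
        phases = detect_uniparental_phases(bouts, 10.0, _meta())
        assert len(phases) == 1
        assert phases[0].onset == T0 + pd.Timedelta(hours=10)
        assert phases[0].end == T0 + pd.Timedelta(hours=70)

    def test_two_phases_with_interleaved_biparental_period(self):
        bouts = (
            [_bout(0, 10, "F"), _bout(10, 20, "M"), _bout(20, 70, "F")]  # temporal
            + [_bout(70, 80, "M"), _bout(80, 90, "F"), _bout(90, 100, "M")]
            + [_bout(100, 160, "F")]  # permanent
        )
        phases = detect_uniparental_phases(bouts, 10.0, _meta())
        assert len(phases) == 2
        assert phases[0].cause == CAUSE_TEMPORAL
        assert phases[1].cause == CAUSE_NATURAL

    def test_hatch_trim_6h(self):
        meta = _meta(hatch_start=T0 + pd.Timedelta(hours=58))
        bouts = [_bout(0, 10, "F"), _bout(10, 20, "M"), _bout(20, 60, "F")]
        phases = detect_uniparental_phases(bouts, 10.0, meta)
        assert len(phases) == 1
        assert phases[0].end == T0 + pd.Timedelta(hours=52)

    def test_chicks_found_trim_24h(self):
        meta = _meta(chicks_found=T0 + pd.Timedelta(hours=80))
        bouts = [_bout(0, 10, "F"), _bout(10, 20, "M"), _bout(20, 60, "F")]
        phases = detect_uniparental_phases(bouts, 10.0, meta)
        assert phases[0].end == T0 + pd.Timedelta(hours=56)

    def test_trim_can_disqualify_phase(self):
        meta = _meta(hatch_start=T0 + pd.Timedelta(hours=52))
        bouts = [_bout(0, 10, "F"), _bout(10, 20, "M"), _bout(20, 60, "F")]
        # trimmed span end 46 h, remainder 16 h < 20 h
        assert detect_uniparental_phases(bouts, 10.0, meta) == []

    def test_censored_when_recording_ends_mid_phase(self):
        bouts = [_bout(0, 10, "F"), _bout(10, 20, "M"), _bout(20, 60, "F")]
        phases = detect_uniparental_phases(
            bouts, 10.0, _meta(), recording_end=T0 + pd.Timedelta(hours=60)
        )
        assert phases[0].censored

    def test_censored_start_when_record_opens_solo(self):
        bouts = [_bout(0, 50, "M")]
        phases = detect_uniparental_phases(bouts, 10.0, _meta())
        assert len(phases) == 1
        assert phases[0].censored_start

    def test_qualify_multiple_is_switchable(self):
        bouts = [_bout(0, 10, "F"), _bout(10, 20, "M"), _bout(20, 45, "F")]
        loose = PhaseParams(qualify_multiple=1.0)
        phases = detect_uniparental_phases(bouts, 10.0, _meta(), loose)
        assert len(phases) == 1  # remainder 15 h >= 1 x 10 h


class TestPhaseMetrics:
    def _phase(self, start_h, end_h):
        from unicub.data_model import UniparentalPhase

        return UniparentalPhase("n", "F", T0 + pd.Timedelta(hours=start_h),
                                T0 + pd.Timedelta(hours=end_h))

    def test_start_fraction_71pct(self):
        frac, _ = phase_metrics(self._phase(14.2 * 24, 16 * 24), T0, REF)
        assert frac == pytest.approx(71.0)

    def test_start_fraction_above_100_allowed(self):
        frac, _ = phase_metrics(self._phase(22 * 24, 23 * 24), T0, REF)
        assert frac == pytest.approx(110.0)

    def test_duration_72h_is_3_days(self):
        _, dur = phase_metrics(self._phase(0.0 + 24, 24 + 72), T0, REF)
        assert dur == pytest.approx(3.0)

    def test_negative_fraction_warns(self):
        phase = self._phase(5, 40)
        with pytest.warns(UserWarning, match="anomaly"):
            phase_metrics(phase, T0 + pd.Timedelta(days=2), REF)


class TestClassifyCause:
    def _phase(self):
        from unicub.data_model import UniparentalPhase

        return UniparentalPhase(
            "n", "F",
            T0 + pd.Timedelta(hours=202), T0 + pd.Timedelta(hours=240),
            onset=T0 + pd.Timedelta(hours=192),
        )

    def test_removal_event(self):
        meta = _meta(events=[(T0 + pd.Timedelta(hours=190), "removal")])
        assert classify_cause(self._phase(), meta, []) == CAUSE_REMOVAL

    def test_capture_within_window(self):
        meta = _meta(events=[(T0 + pd.Timedelta(hours=186), "capture")])
        assert classify_cause(self._phase(), meta, []) == CAUSE_CAPTURE

    def test_capture_outside_window_ignored(self):
        meta = _meta(events=[(T0 + pd.Timedelta(hours=100), "capture")])
        assert classify_cause(self._phase(), meta, []) == CAUSE_NATURAL

    def test_temporal_when_biparental_resumes(self):
        after = [_bout(240, 250, "M"), _bout(250, 260, "F")]
        assert classify_cause(self._phase(), _meta(), after) == CAUSE_TEMPORAL

    def test_natural_otherwise(self):
        assert classify_cause(self._phase(), _meta(), []) == CAUSE_NATURAL


class TestRecoveryOnSynthetic:
    """Smaller sibling of the acceptance recovery check (30 nests)."""

    def _run(self, cfg):
        ds, ledger = generate_dataset(cfg)
        params = ExtractionParams(smooth_window_min=1.0)
        detected = {}
        for nid in ds.nest_ids:
            meta = ds.metadata[nid]
            states = classify_incubation(ds.temperature[nid], params,
                                         longitude=meta.longitude)
            bouts = segment_bouts(states, ds.rfid[nid], params, tag_sex=meta.tag_map)
            detected[nid] = detect_uniparental_phases(
                bouts, cfg.median_bout_h, meta,
                recording_end=ds.temperature[nid].rows["timestamp_utc"].iloc[-1],
            )
        return ds, ledger, detected

    def test_no_desertion_no_phases(self):
        cfg = SimConfig(n_nests=10, sampling_interval_s=120,
                        typical_incubation_period_d=10, desertion_prob=0.0, seed=21)
        _, _, detected = self._run(cfg)
        assert all(len(v) == 0 for v in detected.values())

    def test_injected_desertions_recovered(self):
        cfg = SimConfig(n_nests=30, sampling_interval_s=120,
                        typical_incubation_period_d=12, desertion_prob=1.0,
                        desertion_day_range=(3, 6), solo_days_range=(2.5, 5), seed=22)
        ds, ledger, detected = self._run(cfg)
        truth = ledger.nests.set_index("nest_id")
        median = pd.Timedelta(hours=cfg.median_bout_h)
        hits = 0
        qualifying = 0
        for nid in ds.nest_ids:
            row = truth.loc[nid]
            if not row["deserted"]:
                continue
            span = row["solo_end_utc"] - row["solo_start_utc"]
            if span < 3 * median:
                continue
            qualifying += 1
            phases = detected[nid]
            if not phases:
                continue
            p = phases[-1]
            assert p.sex == row["solo_sex"]
            # phase start within one median bout of (solo onset + median)
            expected_start = row["solo_start_utc"] + median
            assert abs(p.start - expected_start) <= median
            hits += 1
        assert qualifying > 0
        assert hits / qualifying >= 0.95
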