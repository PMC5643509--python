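import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unicub.data_model import Bout, NestMetadata, RfidTrace, SpeciesReference, TemperatureTrace, UnusableTraceError
from unicub.extraction import (
    EstimationError,
    ExtractionParams,
    IncubationStateSeries,
    classify_incubation,
    estimate_incubation_start,
    local_solar_time,
    population_median_bout,
    segment_bouts,
)
from unicub.synthetic import SimConfig, simulate_nest

from conftest import make_trace_frame

T0 = pd.Timestamp("2015-06-01 12:00:00")


class TestLocalSolarTime:
    def test_zero_longitude_identity(self):
        assert local_solar_time(T0, 0.0) == T0

    def test_barrow_longitude_offset(self):
        # -156.65 deg -> -156.65 * 24/360 h
        expected = T0 + pd.Timedelta(hours=-156.65 * 24.0 / 360.0)
        got = local_solar_time(T0, -156.65)
        assert got == expected
        assert got.round("s") == pd.Timestamp("2015-06-01 01:33:24")

    def test_chukotka_longitude_offset(self):
        t = pd.Timestamp("2015-06-01 00:00:00")
        got = local_solar_time(t, 177.67)
        assert got == t + pd.Timedelta(hours=177.67 * 24.0 / 360.0)
        assert got.round("s") == pd.Timestamp("2015-06-01 11:50:41")

    def test_out_of_range_longitude(self):
        with pytest.raises(ValueError, match="longitude"):
            local_solar_time(T0, 181.0)

    def test_vectorized_over_series(self):
        ts = pd.Series(pd.date_range("2015-06-01", periods=3, freq="h"))
        out = local_solar_time(ts, -90.0)
        assert (out == ts - pd.Timedelta(hours=6)).all()


class TestClassifyIncubation:
    def test_constant_separation_all_incubated(self):
        trace = TemperatureTrace("n", make_trace_frame(T0, 100, 60, 35.0, 5.0))
        states = classify_incubation(trace, ExtractionParams(margin_c=3.0))
        assert states.df["incubated"].all()
        assert (states.df.loc[states.df["incubated"], "attending"] == "unknown").all()

    def test_nest_equals_surface_none_incubated(self):
        trace = TemperatureTrace("n", make_trace_frame(T0, 100, 60, 20.0, 20.0))
        states = classify_incubation(trace, ExtractionParams())
        assert not states.df["incubated"].any()

    def test_all_missing_temperatures_unusable(self):
        rows = make_trace_frame(T0, 10, 60, 35.0, 5.0)
        rows["nest_temp_c"] = np.nan
        with pytest.raises(UnusableTraceError):
            classify_incubation(TemperatureTrace("n", rows), ExtractionParams())

    def test_idempotent(self):
        trace = TemperatureTrace("n", make_trace_frame(T0, 50, 60, 35.0, 5.0))
        a = classify_incubation(trace, ExtractionParams())
        b = classify_incubation(trace, ExtractionParams())
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_square_wave_transitions_within_one_smooth_window(self):
        # attended 2 h at 35 C, 1 h exponential decay toward ambient, repeated
        cfg = SimConfig(
            n_nests=1, sampling_interval_s=60, typical_incubation_period_d=2,
            median_bout_h=2.0, bout_log_sd=0.0, exchange_gap_min=60.0, seed=0,
        )
        trace, _, meta, ledger = simulate_nest(cfg, seed=0)
        params = ExtractionParams(smooth_window_min=5.0, recess_tolerance_min=10.0)
        states = classify_incubation(trace, params, longitude=meta.longitude)
        truth = ledger.attending_at("n000", trace.rows["timestamp_utc"]) != "none"
        got = states.df["incubated"].to_numpy()
        # all mismatches must hug a true switch point
        switch = np.flatnonzero(np.diff(truth.astype(int)) != 0)
        tolerance_samples = 5  # one smooth window at 60-s sampling
        for i in np.flatnonzero(got != truth):
            assert np.min(np.abs(switch - i)) <= tolerance_samples

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-10, 45, allow_nan=False),
                st.floats(-10, 45, allow_nan=False),
            ),
            min_size=2,
            max_size=80,
        ),
        margin=st.floats(0.5, 6.0),
    )
    def test_margin_only_mode_matches_per_reading_oracle(self, data, margin):
        nest = [a for a, _ in data]
        surface = [b for _, b in data]
        rows = make_trace_frame(T0, len(data), 60, 1.0, 1.0)
        rows["nest_temp_c"] = nest
        rows["surface_temp_c"] = surface
        params = ExtractionParams(
            margin_c=margin,
            surface_window_min=0.5,  # < one sample: raw comparison
            smooth_window_min=0.5,
            steep_slope_c_per_min=None,
        )
        states = classify_incubation(TemperatureTrace("n", rows), params)
        oracle = [n - s >= margin for n, s in zip(nest, surface)]
        assert states.df["incubated"].tolist() == oracle


def _states_from_mask(mask, dt_s=60):
    ts = T0 + pd.to_timedelta(np.arange(len(mask)) * dt_s, unit="s")
    df = pd.DataFrame(
        {
            "timestamp_utc": ts,
            "timestamp_local": ts,
            "incubated": np.asarray(mask, dtype=bool),
            "attending": np.where(mask, "unknown", "none"),
        }
    )
    return IncubationStateSeries("n", df)


def _rfid(times, tags):
    return RfidTrace("n", pd.DataFrame({"timestamp_utc": times, "tag_id": tags}))


class TestSegmentBouts:
    def test_alternating_tags_give_two_bouts(self):
        n = 24 * 60  # 24 h at 1-min cadence, continuously incubated
        states = _states_from_mask(np.ones(n, dtype=bool))
        det_times = [T0 + pd.Timedelta(minutes=m) for m in range(0, n, 5)]
        tags = ["tf" if t < T0 + pd.Timedelta(hours=12) else "tm" for t in det_times]
        bouts = segment_bouts(states, _rfid(det_times, tags),
                              tag_sex={"tf": "F", "tm": "M"})
        assert [b.attending for b in bouts] == ["F", "M"]
        assert bouts[0].length_h == pytest.approx(12.0, abs=0.1)
        assert bouts[1].length_h == pytest.approx(12.0, abs=0.1)
        assert bouts[0].end == bouts[1].start

    def test_no_rfid_gives_unknown(self):
        states = _states_from_mask(np.ones(100, dtype=bool))
        bouts = segment_bouts(states, None)
        assert len(bouts) == 1
        assert bouts[0].attending == "unknown"

    def test_thirty_minute_gap_merged_with_60min_tolerance(self):
        mask = np.ones(240, dtype=bool)
        mask[100:130] = False  # 30-min gap at 1-min cadence
        states = _states_from_mask(mask)
        bouts = segment_bouts(states, None,
                              ExtractionParams(recess_tolerance_min=60.0))
        assert len(bouts) == 1
        assert bouts[0].length_h == pytest.approx(4.0, abs=0.05)

    def test_long_gap_splits_with_small_tolerance(self):
        mask = np.ones(240, dtype=bool)
        mask[100:130] = False
        states = _states_from_mask(mask)
        bouts = segment_bouts(states, None,
                              ExtractionParams(recess_tolerance_min=10.0))
        assert len(bouts) == 2

    def test_majority_labelling_with_tie_broken_by_first_detection(self):
        states = _states_from_mask(np.ones(60, dtype=bool))
        # one detection each, interleaved so no clean change-over split exists
        det_times = [T0 + pd.Timedelta(minutes=m) for m in (5, 30)]
        bouts = segment_bouts(states, _rfid(det_times, ["tm", "tf"]),
                              tag_sex={"tf": "F", "tm": "M"})
        # split at the change-over produces one bout per tag here
        assert [b.attending for b in bouts] == ["M", "F"]

    def test_bouts_non_overlapping_on_synthetic(self, small_noisy_dataset, exact_params):
        _, ds, _ = small_noisy_dataset
        nid = ds.nest_ids[0]
        meta = ds.metadata[nid]
        states = classify_incubation(ds.temperature[nid], longitude=meta.longitude)
        bouts = segment_bouts(states, ds.rfid[nid], tag_sex=meta.tag_map)
        for a, b in zip(bouts, bouts[1:]):
            assert a.end <= b.start
        span = (ds.temperature[nid].rows["timestamp_utc"].iloc[-1]
                - ds.temperature[nid].rows["timestamp_utc"].iloc[0])
        total = sum((b.end - b.start for b in bouts), pd.Timedelta(0))
        assert total <= span + pd.Timedelta(minutes=1)


class TestExactRecovery:
    def test_noise_free_bouts_match_truth_ledger(self, noise_free_dataset, exact_params):
        _, ds, ledger = noise_free_dataset
        for nid in ds.nest_ids:
            meta = ds.metadata[nid]
            states = classify_incubation(ds.temperature[nid], exact_params,
                                         longitude=meta.longitude)
            bouts = segment_bouts(states, ds.rfid[nid], exact_params,
                                  tag_sex=meta.tag_map)
            got = {(b.start, b.end, b.attending) for b in bouts}
            tb = ledger.nest_bouts(nid)
            want = set(zip(tb["start_utc"], tb["end_utc"], tb["sex"]))
            assert got == want


class TestPopulationMedianBout:
    def _mk(self, hours):
        return [Bout("n", T0, T0 + pd.Timedelta(hours=h)) for h in hours]

    def test_odd_count(self):
        assert population_median_bout(self._mk([10, 12, 14])) == 12.0

    def test_even_count_midpoint(self):
        assert population_median_bout(self._mk([10, 12])) == 11.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            population_median_bout([])

    def test_lognormal_draws_match_sort_oracle(self):
        rng = np.random.default_rng(42)
        hours = np.exp(rng.normal(np.log(11.0), 0.3, 1001))
        bouts = self._mk(hours)
        srt = np.sort(hours)
        oracle = srt[len(srt) // 2]  # odd count
        assert population_median_bout(bouts) == pytest.approx(oracle, rel=1e-9)


class TestEstimateIncubationStart:
    REF = SpeciesReference("sp", "pop", 21.0, 11.0)

    def _meta(self, **kw):
        return NestMetadata("n", "sp", "pop", 71.0, -156.0, **kw)

    def test_laying_rule(self):
        meta = self._meta(first_egg_date=pd.Timestamp("2015-05-01"), clutch_size=4)
        assert estimate_incubation_start(meta, self.REF) == pd.Timestamp("2015-05-04")

    def test_hatch_minus_typical_period(self):
        meta = self._meta(hatch_start=pd.Timestamp("2015-06-01"))
        assert estimate_incubation_start(meta, self.REF) == pd.Timestamp("2015-05-11")

    def test_direct_observation_takes_precedence(self):
        meta = self._meta(
            incubation_start=pd.Timestamp("2015-05-02 06:00"),
            first_egg_date=pd.Timestamp("2015-05-01"),
            clutch_size=4,
        )
        assert estimate_incubation_start(meta, self.REF) == pd.Timestamp("2015-05-02 06:00")

    def test_flotation_lookup(self):
        meta = self._meta(flotation_date=pd.Timestamp("2015-05-20"), flotation_stage="s3")
        got = estimate_incubation_start(meta, self.REF, flotation_lookup={"s3": 9.0})
        assert got == pd.Timestamp("2015-05-11")

    def test_population_year_median_fallback(self):
        meta = self._meta(year=2015)
        got = estimate_incubation_start(
            meta, self.REF, population_medians={("pop", 2015): pd.Timestamp("2015-05-15")}
        )
        assert got == pd.Timestamp("2015-05-15")

    def test_no_pathway_raises(self):
        with pytest.raises(EstimationError, match="n"):
            estimate_incubation_start(self._meta(), self.REF)
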