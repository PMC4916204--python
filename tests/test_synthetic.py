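import numpy as np
import pandas as pd
import pytest

from spatbeat import (
    CohortConfig,
    ParameterError,
    ConfigurationError,
    RampProtocol,
    VideoScene,
    make_beat_train,
    make_cohort,
    make_temp_trace,
    make_trace,
    make_video,
)


class TestMakeBeatTrain:
    def test_constant_rate_no_jitter_is_exact_grid(self):
        train = make_beat_train(80.0, duration_s=60.0)
        assert len(train) == 80
        assert np.allclose(np.diff(train.event_times) * 1000.0, 750.0)

    def test_zero_rate_emits_no_events(self):
        assert len(make_beat_train(0.0, duration_s=60.0)) == 0
        assert len(make_beat_train(lambda t: 0.0, duration_s=30.0)) == 0

    def test_jittered_mean_ibi_matches_generating_mean(self):
        # 60 beats/min, 20 ms jitter: mean IBI within 1000 +/- 5 ms over 20 seeds
        means = []
        for seed in range(20):
            train = make_beat_train(60.0, 600.0, jitter_sd_ms=20.0, seed=seed)
            means.append(np.mean(np.diff(train.event_times)) * 1000.0)
        assert abs(np.mean(means) - 1000.0) < 5.0

    def test_rate_consistency_over_replicates(self):
        # mean event count over 50 trains at rate r in 600 s within 2% of 10*r
        r = 72.0
        counts = [
            len(make_beat_train(r, 600.0, jitter_sd_ms=25.0, seed=s))
            for s in range(50)
        ]
        assert abs(np.mean(counts) - 10 * r) <= 0.02 * 10 * r

    def test_piecewise_profile_respects_silence(self):
        hr = lambda t: 60.0 if t < 10.0 else 0.0
        train = make_beat_train(hr, duration_s=30.0)
        assert np.all(train.event_times < 10.0)
        assert len(train) == 10

    def test_events_strictly_increasing_under_heavy_jitter(self):
        train = make_beat_train(90.0, 120.0, jitter_sd_ms=400.0, seed=3)
        diffs = np.diff(train.event_times)
        assert np.all(diffs > 0)
        assert np.all(diffs * 1000.0 >= 150.0 - 1e-9)  # refractory floor

    def test_negative_parameters_rejected(self):
        with pytest.raises(ParameterError):
            make_beat_train(60.0, 10.0, jitter_sd_ms=-1.0)
        with pytest.raises(ParameterError):
            make_beat_train(60.0, 10.0, refractory_ms=-5.0)


class TestMakeVideo:
    def test_no_beats_no_noise_gives_identical_frames(self):
        scene = VideoScene(background_noise_sd=0.0)
        frames, gt = make_video(make_beat_train(0.0, 1.0), scene, duration_s=1.0)
        assert gt.size == 0
        assert np.all(frames.frames == frames.frames[0])

    def test_single_pulse_peaks_near_beat_time(self):
        scene = VideoScene(background_noise_sd=0.0)
        from spatbeat import BeatSeries

        frames, _ = make_video(BeatSeries(np.array([1.0])), scene, duration_s=2.5)
        r, c = scene.heart_center
        series = frames.frames[:, int(r), int(c), 0].astype(float)
        peaks = [
            i
            for i in range(1, len(series) - 1)
            if series[i] > series[i - 1] and series[i] >= series[i + 1]
        ]
        assert len(peaks) == 1
        assert abs(frames.times[peaks[0]] - 1.0) <= 0.1

    def test_scene_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            VideoScene(heart_center=(64.0, 64.0), heart_radius=60.0)  # escapes shell
        with pytest.raises(ConfigurationError):
            VideoScene(reference_point=(64.0, 64.0))  # inside shell


class TestMakeTrace:
    def test_trace_peak_count_matches_beats(self):
        train = make_beat_train(40.0, 30.0)
        trace = make_trace(train, 30.0, noise_sd=0.0)
        above = trace.values > 0.5
        rises = np.count_nonzero(above[1:] & ~above[:-1])
        assert rises == len(train)


class TestMakeTempTrace:
    def test_settles_within_tolerance_inside_settle_time(self, default_protocol):
        temp = make_temp_trace(default_protocol, noise_sd=0.0, seed=0)
        for step, (t0, t1) in zip(
            default_protocol.steps, default_protocol.step_windows()
        ):
            sel = (temp.times >= t0 + 80.0) & (temp.times < t1)
            assert np.all(np.abs(temp.celsius[sel] - step.set_point) <= 1.0)


class TestMakeCohort:
    def test_noise_free_cohort_reproduces_linear_hr_exactly(
        self, noise_free_config, default_protocol
    ):
        ds = make_cohort(noise_free_config, default_protocol, seed=0)
        expected = 80.0 + 5.0 * (ds.segments["set_point"] - 22.0)
        assert np.allclose(ds.segments["hr_active"], expected, atol=1e-9)
        assert not ds.segments["asystole"].any()

    def test_sharp_arrest_threshold_floors_warm_group_at_10C(self):
        config = CohortConfig(
            arrest_threshold_mean={"Ta10": -1000.0, "Ta22": 13.0},
            arrest_threshold_sd={"Ta10": 0.0, "Ta22": 0.0},
        )
        ds = make_cohort(config, seed=1)
        ta22 = ds.segments[ds.segments["group"] == "Ta22"]
        at10 = ta22[(ta22["set_point"] == 10.0) & (ta22["phase"] == "cooling")]
        at22 = ta22[(ta22["set_point"] == 22.0) & (ta22["phase"] == "cooling")]
        assert at10["asystole"].all() and len(at10) == 8
        assert not at22["asystole"].any()

    def test_identical_seed_gives_identical_dataset(self, default_protocol):
        a = make_cohort(seed=42)
        b = make_cohort(seed=42)
        pd.testing.assert_frame_equal(a.segments, b.segments)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for spat in a.beats:
            assert np.array_equal(a.beats[spat].event_times, b.beats[spat].event_times)

    def test_different_seeds_differ(self):
        a = make_cohort(seed=1)
        b = make_cohort(seed=2)
        assert not a.truth["intercept"].equals(b.truth["intercept"])

    def test_asystole_monotone_in_cooling_phase(self):
        # once asystolic during cooling, a spat stays asystolic at colder steps
        for seed in range(5):
            ds = make_cohort(seed=seed)
            cooling = ds.segments[ds.segments["phase"] == "cooling"]
            for _, sub in cooling.groupby("spat_id"):
                flags = sub.sort_values("set_point", ascending=False)["asystole"]
                assert flags.astype(int).is_monotonic_increasing

    def test_residual_tail_is_sporadic_then_silent(self):
        config = CohortConfig(
            arrest_threshold_mean={"Ta10": -1000.0, "Ta22": 15.0},
            arrest_threshold_sd={"Ta10": 0.0, "Ta22": 0.0},
        )
        ds = make_cohort(config, seed=7)
        ta22 = ds.segments[
            (ds.segments["group"] == "Ta22") & (ds.segments["phase"] == "cooling")
        ]
        first_arrest = ta22[ta22["set_point"] == 14.0]
        assert (first_arrest["beat_count"] <= 5).all()
        deeper = ta22[ta22["set_point"] < 14.0]
        assert (deeper["beat_count"] == 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_per_group=0)
        with pytest.raises(ConfigurationError):
            CohortConfig(intercept_sd=-1.0)
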