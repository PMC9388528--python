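"""Event detection, trial validity rules, scoring and aggregation."""

import numpy as np
import pandas as pd
import pytest

from gazeprs.oculomotor import (
    GazeRecording,
    SaccadeEvent,
    Trial,
    TrialMetrics,
    aggregate_subject,
    compute_kinematics,
    detect_blinks,
    detect_saccades,
    parse_trials,
    read_asc,
    score_saccade_trial,
    summarize_fixation_task,
    summarize_saccade_task,
    summarize_spem_task,
    validate_trial,
)
from gazeprs.simulate import GazeSimConfig, SubjectParams, make_task, simulate_gaze_session


def make_recording(x, y=None, blink=None, messages=None, rate=1000.0):
    n = len(x)
    samples = pd.DataFrame(
        {
            "time_ms": np.arange(n) * 1000.0 / rate,
            "x_deg": np.asarray(x, dtype=float),
            "y_deg": np.zeros(n) if y is None else np.asarray(y, dtype=float),
            "blink": np.zeros(n, dtype=int) if blink is None else np.asarray(blink),
        }
    )
    msgs = pd.DataFrame(messages or [], columns=["time_ms", "event"])
    return GazeRecording(samples=samples, messages=msgs, sampling_rate=rate)


def trace_from_velocity(profile_deg_per_s, lead_ms=500, trail_ms=500):
    """Integrate a per-ms velocity profile into a position trace."""
    v = np.concatenate(
        [np.zeros(lead_ms), np.asarray(profile_deg_per_s), np.zeros(trail_ms)]
    )
    return np.cumsum(v) / 1000.0


def trapezoid(peak, accel=3000.0, plateau_ms=60):
    rise = np.arange(0, peak, accel / 1000.0)
    return np.concatenate([rise, np.full(plateau_ms, peak), rise[::-1]])


class TestKinematics:
    def test_constant_position_has_zero_velocity(self):
        kin = compute_kinematics(make_recording(np.full(1000, 3.0)))
        assert np.allclose(kin.speed, 0.0, atol=1e-9)

    def test_linear_ramp_velocity(self):
        x = 10.0 * np.arange(2000) / 1000.0  # 10 deg/s
        kin = compute_kinematics(make_recording(x))
        mid = kin.speed[100:-100]
        assert np.allclose(mid, 10.0, atol=1e-6)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            compute_kinematics(make_recording(np.zeros(4)))

    def test_simulated_peak_velocity_recovered(self):
        cfg = GazeSimConfig(noise_sd=0.0, blink_rate=0.0, seed=1)
        session = simulate_gaze_session(make_task("prosaccade"), cfg)
        det = detect_saccades(session.recording)
        truth = session.events.sort_values("onset_ms")
        det = sorted(det, key=lambda e: e.onset_ms)
        for ev, (_, row) in zip(det, truth.iterrows()):
            assert ev.peak_velocity == pytest.approx(row["peak_velocity"], rel=0.08)


class TestSaccadeDetection:
    def test_flat_noisy_trace_yields_nothing(self, rng):
        x = rng.normal(0, 0.05, 5000)
        assert detect_saccades(make_recording(x)) == []

    def test_velocity_below_both_criteria_never_detected(self):
        # peak 59 deg/s with acceleration capped at 3000 < 3800
        x = trace_from_velocity(trapezoid(59.0))
        assert detect_saccades(make_recording(x)) == []

    def test_velocity_at_high_threshold_always_detected(self):
        x = trace_from_velocity(trapezoid(61.0))
        events = detect_saccades(make_recording(x))
        assert len(events) == 1
        assert events[0].amplitude > 1.0

    def test_accel_route_detects_sharp_sub60_steps(self):
        # a sharp velocity step to 50 deg/s never reaches the 60 deg/s
        # criterion, but its acceleration transient exceeds 3800 deg/s^2
        # while velocity is above 22 deg/s
        x = trace_from_velocity(np.full(80, 50.0))
        events = detect_saccades(make_recording(x))
        assert len(events) == 1

    def test_small_amplitude_rejected(self):
        # 0.8 deg microsaccade: raised-cosine, peak 80 deg/s
        dur = int(2 * 0.8 / 80.0 * 1000)
        u = np.arange(1, dur + 1) / dur
        v = 80.0 / 2 * (1 - np.cos(2 * np.pi * u))
        x = trace_from_velocity(v)
        assert abs(x[-1] - 0.8) < 0.01
        assert detect_saccades(make_recording(x)) == []

    def test_planted_saccade_onset_and_amplitude(self):
        cfg = GazeSimConfig(noise_sd=0.0, blink_rate=0.0, seed=2)
        session = simulate_gaze_session(make_task("prosaccade"), cfg)
        det = detect_saccades(session.recording)
        truth = session.events
        assert len(det) == len(truth)
        d_on = np.sort([e.onset_ms for e in det])
        t_on = np.sort(truth["onset_ms"].to_numpy())
        assert np.max(np.abs(d_on - t_on)) <= 2.0
        d_amp = np.array([e.amplitude for e in sorted(det, key=lambda e: e.onset_ms)])
        t_amp = truth.sort_values("onset_ms")["amplitude"].to_numpy()
        assert np.max(np.abs(d_amp - t_amp) / t_amp) < 0.05


class TestBlinkDetection:
    def test_no_flags_no_blinks(self):
        assert detect_blinks(make_recording(np.zeros(500))) == []

    def test_single_run_extent_with_padding(self):
        blink = np.zeros(1000, dtype=int)
        blink[400:520] = 1
        events = detect_blinks(make_recording(np.zeros(1000), blink=blink))
        assert len(events) == 1
        lo, hi = events[0]
        assert lo == pytest.approx(350.0)
        assert hi == pytest.approx(569.0)

    def test_nearby_runs_merge_after_padding(self):
        blink = np.zeros(1000, dtype=int)
        blink[300:350] = 1
        blink[360:400] = 1  # 10 ms apart; 50 ms padding overlaps
        events = detect_blinks(make_recording(np.zeros(1000), blink=blink))
        assert len(events) == 1


class TestTrialValidity:
    @staticmethod
    def make_trial(target_onset=2000.0, target_x=9.63):
        return Trial(
            index=1,
            side="right" if target_x > 0 else "left",
            target_x=target_x,
            fixation_onset_ms=target_onset - 1500,
            target_onset_ms=target_onset,
            target_offset_ms=target_onset + 1000,
        )

    @staticmethod
    def saccade(onset, offset, start_x, end_x, peak_v=300.0):
        return SaccadeEvent(
            onset_ms=onset,
            offset_ms=offset,
            amplitude=abs(end_x - start_x),
            peak_velocity=peak_v,
            peak_acceleration=20000.0,
            direction=int(np.sign(end_x - start_x)),
            start_x=start_x,
            end_x=end_x,
        )

    def test_off_centre_fixation_invalid(self):
        rec = make_recording(np.full(4000, 4.0))  # 4 deg off centre
        trial = self.make_trial()
        validate_trial(trial, rec, [], [])
        assert not trial.valid and trial.invalid_reason == "off_fixation"

    def test_anticipatory_latency_invalid(self):
        rec = make_recording(np.zeros(4000))
        trial = self.make_trial()
        sac = self.saccade(2060.0, 2110.0, 0.0, 9.63)  # latency 60 < 80
        validate_trial(trial, rec, [sac], [])
        assert not trial.valid and trial.invalid_reason == "anticipatory"

    def test_no_saccade_invalid(self):
        rec = make_recording(np.zeros(4000))
        trial = self.make_trial()
        validate_trial(trial, rec, [], [])
        assert not trial.valid and trial.invalid_reason == "no_saccade"

    def test_blink_in_fixation_window_invalid(self):
        rec = make_recording(np.zeros(4000))
        trial = self.make_trial()
        sac = self.saccade(2200.0, 2250.0, 0.0, 9.63)
        validate_trial(trial, rec, [sac], [(1950.0, 1990.0)])
        assert not trial.valid and trial.invalid_reason == "blink_in_fixation"

    def test_adding_artifact_never_revalidates(self):
        """A valid trial made dirty (blink in the fixation window) must
        turn invalid — validity is monotone in artifacts."""
        rec = make_recording(np.zeros(4000))
        trial = self.make_trial()
        sac = self.saccade(2200.0, 2250.0, 0.0, 9.63)
        validate_trial(trial, rec, [sac], [])
        assert trial.valid
        dirty = self.make_trial()
        validate_trial(dirty, rec, [sac], [(1920.0, 1930.0)])
        assert not dirty.valid

    def test_initial_saccade_after_timeout_invalid(self):
        rec = make_recording(np.zeros(5000))
        trial = self.make_trial()
        sac = self.saccade(2950.0, 3050.0, 0.0, 9.63)  # ends after offset
        validate_trial(trial, rec, [sac], [])
        assert not trial.valid and trial.invalid_reason == "initial_saccade_too_late"


class TestTrialScoring:
    def test_exact_landing_has_unit_gain_and_zero_error(self):
        trial = TestTrialValidity.make_trial()
        sac = TestTrialValidity.saccade(2200.0, 2250.0, 0.0, 9.63)
        trial.events = [sac]
        trial.valid = True
        m = score_saccade_trial(trial, "prosaccade")
        assert m.amplitude_gain == pytest.approx(100.0)
        assert m.spatial_error == pytest.approx(0.0)
        assert m.direction_correct

    @pytest.mark.parametrize("gain", [0.8, 0.95, 1.1])
    def test_gain_error_duality_for_centre_saccades(self, gain):
        """A saccade from centre landing at gain g implies spatial error
        |g - 100| percent in the prosaccade task."""
        trial = TestTrialValidity.make_trial()
        sac = TestTrialValidity.saccade(2200.0, 2250.0, 0.0, 9.63 * gain)
        trial.events = [sac]
        trial.valid = True
        m = score_saccade_trial(trial, "prosaccade")
        assert m.spatial_error == pytest.approx(abs(m.amplitude_gain - 100.0))

    def test_antisaccade_mirror_saccade_is_correct(self):
        trial = TestTrialValidity.make_trial(target_x=9.63)
        sac = TestTrialValidity.saccade(2200.0, 2250.0, 0.0, -9.63)
        trial.events = [sac]
        trial.valid = True
        m = score_saccade_trial(trial, "antisaccade")
        assert m.direction_correct
        assert m.spatial_error == pytest.approx(0.0)

    def test_antisaccade_error_with_midline_crossing_correction(self):
        trial = TestTrialValidity.make_trial(target_x=9.63)
        wrong = TestTrialValidity.saccade(2200.0, 2250.0, 0.0, 9.0)
        back = TestTrialValidity.saccade(2400.0, 2460.0, 9.0, -8.5)
        trial.events = [wrong, back]
        trial.valid = True
        m = score_saccade_trial(trial, "antisaccade")
        assert not m.direction_correct
        assert m.corrected

    def test_uncrossed_return_is_not_a_correction(self):
        trial = TestTrialValidity.make_trial(target_x=9.63)
        wrong = TestTrialValidity.saccade(2200.0, 2250.0, 0.0, 9.0)
        partial = TestTrialValidity.saccade(2400.0, 2460.0, 9.0, 2.0)
        trial.events = [wrong, partial]
        trial.valid = True
        m = score_saccade_trial(trial, "antisaccade")
        assert m.corrected is False

    def test_invalid_trial_rejected(self):
        trial = TestTrialValidity.make_trial()
        with pytest.raises(ValueError):
            score_saccade_trial(trial, "prosaccade")


def _metrics(index, latency=200.0, correct=True, corrected=None):
    return TrialMetrics(
        index=index,
        latency_ms=latency,
        amplitude_gain=95.0,
        spatial_error=8.0,
        peak_velocity=350.0,
        adjusted_peak_velocity=3.8,
        direction_correct=correct,
        corrected=corrected,
    )


class TestAggregation:
    def test_six_correct_trials_leave_outcomes_absent(self):
        metrics = [_metrics(i) for i in range(6)]
        summary = aggregate_subject(pro_metrics=metrics)
        assert np.isnan(summary.prosaccade_latency)
        assert summary.n_valid_correct_pro == 6

    def test_seven_correct_trials_produce_outcomes(self):
        metrics = [_metrics(i, latency=200.0 + i) for i in range(7)]
        summary = aggregate_subject(pro_metrics=metrics)
        assert summary.prosaccade_latency == pytest.approx(203.0)

    def test_four_errors_leave_correction_rate_absent(self):
        anti = [_metrics(i) for i in range(6)] + [
            _metrics(6 + i, correct=False, corrected=True) for i in range(4)
        ]
        summary = aggregate_subject(anti_metrics=anti)
        assert summary.antisaccade_error_rate == pytest.approx(40.0)
        assert np.isnan(summary.antisaccade_correction_rate)

    def test_five_errors_all_corrected_give_full_correction_rate(self):
        anti = [_metrics(i) for i in range(10)] + [
            _metrics(10 + i, correct=False, corrected=True) for i in range(5)
        ]
        summary = aggregate_subject(anti_metrics=anti)
        assert summary.antisaccade_correction_rate == pytest.approx(100.0)

    def test_five_errors_none_corrected_leave_rate_absent(self):
        anti = [_metrics(i, correct=False, corrected=False) for i in range(5)]
        summary = aggregate_subject(anti_metrics=anti)
        assert np.isnan(summary.antisaccade_correction_rate)

    def test_costs_require_both_latencies(self):
        pro = [_metrics(i, latency=190.0) for i in range(8)]
        anti = [_metrics(i, latency=280.0) for i in range(8)]
        both = aggregate_subject(pro_metrics=pro, anti_metrics=anti)
        assert both.antisaccade_costs == pytest.approx(90.0)
        only_pro = aggregate_subject(pro_metrics=pro)
        assert np.isnan(only_pro.antisaccade_costs)


class TestSessionParsing:
    def test_prosaccade_session_has_thirty_trials(self):
        session = simulate_gaze_session(make_task("prosaccade"), GazeSimConfig(seed=3))
        trials = parse_trials(session.recording, "prosaccade")
        assert len(trials) == 30

    def test_antisaccade_practice_excluded(self):
        session = simulate_gaze_session(make_task("antisaccade"), GazeSimConfig(seed=3))
        trials = parse_trials(session.recording, "antisaccade")
        assert len(trials) == 30
        assert min(t.index for t in trials) == 7

    def test_truncated_session_warns(self):
        session = simulate_gaze_session(make_task("prosaccade"), GazeSimConfig(seed=4))
        rec = session.recording
        cut = rec.samples["time_ms"] < 40_000
        truncated = GazeRecording(
            samples=rec.samples[cut].reset_index(drop=True),
            messages=rec.messages[rec.messages["time_ms"] < 40_000],
            sampling_rate=rec.sampling_rate,
        )
        with pytest.warns(UserWarning, match="truncated"):
            trials = parse_trials(truncated, "prosaccade")
        assert 0 < len(trials) < 30


class TestEndToEnd:
    def test_direction_error_rate_recovered_across_subjects(self):
        """Subject-level error-rate estimates track the generating
        probability across simulated antisaccade sessions."""
        p = 0.3
        rates = []
        n_subjects = 30
        for seed in range(n_subjects):
            cfg = GazeSimConfig(direction_error_prob=p, seed=100 + seed)
            session = simulate_gaze_session(make_task("antisaccade"), cfg)
            _, metrics = summarize_saccade_task(session.recording, "antisaccade")
            if metrics:
                errs = sum(not m.direction_correct for m in metrics)
                rates.append(errs / len(metrics))
        est = float(np.mean(rates))
        n_trials = 30 * len(rates)
        se = np.sqrt(p * (1 - p) / n_trials)
        assert abs(est - p) < 3 * se

    def test_spem_and_fixation_pipeline(self):
        cfg = GazeSimConfig(seed=6)
        sp = simulate_gaze_session(make_task("spem"), cfg, SubjectParams(pursuit_gain=0.8))
        r = summarize_spem_task(sp.recording)
        assert r["velocity_gain"] == pytest.approx(80.0, abs=2.5)
        fx = simulate_gaze_session(make_task("fixation"), cfg)
        f = summarize_fixation_task(fx.recording)
        assert f["spatial_error"] < 0.5
        assert f["n_fixation_periods"] >= 4


class TestASCImporter:
    def test_samples_and_messages_parsed(self, tmp_path):
        lines = ["** header junk", "MSG 1000 TRIAL_START 1"]
        for i in range(400):
            lines.append(f"{1000 + i}\t{0.01 * i:.3f}\t0.000\t500.0")
        lines.append("MSG 1200 TARGET_ON 9.63 0")
        lines.append("1400\t.\t.\t0.0")
        path = tmp_path / "session.asc"
        path.write_text("\n".join(lines) + "\n")
        rec = read_asc(path)
        assert len(rec.samples) == 401
        assert rec.samples["blink"].iloc[-1] == 1
        assert list(rec.messages["event"]) == ["TRIAL_START 1", "TARGET_ON 9.63 0"]
        assert rec.sampling_rate == pytest.approx(1000.0)
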