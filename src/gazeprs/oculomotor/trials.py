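"""Saccade-task trials: parsing, validity rules, scoring and aggregation.

A prosaccade/antisaccade session consists of 30 scored trials (the
antisaccade block is preceded by six practice trials that are excluded).
In each trial the target holds the centre for 1-2 s and then steps to
x = +-9.63 deg for 1 s.  A trial is valid when central fixation started at
least 100 ms before target onset and was no more than 3 deg off the
fixation point, no saccade or blink occurred in that pre-target window,
the initial saccade ended before the target timed out, and its latency was
at least 80 ms.  The initial saccade is the first detected saccade after
target onset; in the antisaccade task a first saccade toward the target is
a direction error, counted as corrected when a later saccade crosses the
midline toward the mirror position before target offset.

Subject-level outcomes are means over qualifying trials; outcomes backed
by fewer than 7 valid-and-correct trials are absent (NaN), never zero.
The direction error rate requires only valid trials; the correction rate
requires at least 5 direction errors and at least one corrective saccade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gazeprs.oculomotor.events import SaccadeEvent, compute_kinematics, detect_blinks, detect_saccades
from gazeprs.oculomotor.recording import GazeRecording

__all__ = [
    "Trial",
    "TrialMetrics",
    "SubjectOculomotorSummary",
    "parse_trials",
    "validate_trial",
    "score_saccade_trial",
    "summarize_saccade_task",
    "aggregate_subject",
    "TARGET_ECCENTRICITY",
]

TARGET_ECCENTRICITY = 9.63  # deg
FIXATION_WINDOW_MS = 100.0
FIXATION_OFF_MAX_DEG = 3.0
LATENCY_MIN_MS = 80.0
MIN_VALID_CORRECT_TRIALS = 7
MIN_DIRECTION_ERRORS = 5
ANTISACCADE_PRACTICE_TRIALS = 6


@dataclass
class Trial:
    """One parsed saccade-task trial with its detected events."""

    index: int
    side: str  # "left" | "right"
    target_x: float
    fixation_onset_ms: float
    target_onset_ms: float
    target_offset_ms: float
    events: list[SaccadeEvent] = field(default_factory=list)
    valid: bool = False
    invalid_reason: str = ""


@dataclass
class TrialMetrics:
    """Scored metrics of one valid trial."""

    index: int
    latency_ms: float
    amplitude_gain: float  # %
    spatial_error: float  # %
    peak_velocity: float  # deg/s
    adjusted_peak_velocity: float  # deg/s per deg
    direction_correct: bool
    corrected: bool | None = None  # antisaccade error trials only


def parse_trials(
    recording: GazeRecording, task: str, n_expected: int = 30
) -> list[Trial]:
    """Split a session into trials from TRIAL_START / TARGET_ON markers.

    The antisaccade block's leading practice trials are excluded from
    scoring.  A truncated session yields fewer trials with a warning.
    """
    if task not in ("prosaccade", "antisaccade"):
        raise ValueError(f"unknown saccade task {task!r}")
    msgs = recording.messages
    trials: list[Trial] = []
    current: dict | None = None
    for _, m in msgs.iterrows():
        t = float(m["time_ms"])
        parts = str(m["event"]).split()
        if not parts:
            continue
        if parts[0] == "TRIAL_START":
            current = {"index": int(parts[1]), "fixation_onset": t, "target_onset": None}
        elif parts[0] == "TARGET_ON" and current is not None:
            x = float(parts[1])
            if x != 0.0:
                current["target_onset"] = t
                current["target_x"] = x
        elif parts[0] == "TRIAL_END" and current is not None:
            if int(parts[1]) != current["index"]:
                raise ValueError(
                    f"marker mismatch: TRIAL_END {parts[1]} inside trial {current['index']}"
                )
            if current["target_onset"] is None:
                warnings.warn(f"trial {current['index']} has no peripheral target; skipped")
            else:
                trials.append(
                    Trial(
                        index=current["index"],
                        side="right" if current["target_x"] > 0 else "left",
                        target_x=current["target_x"],
                        fixation_onset_ms=current["fixation_onset"],
                        target_onset_ms=current["target_onset"],
                        target_offset_ms=current["target_onset"] + 1000.0,
                    )
                )
            current = None
    if task == "antisaccade" and len(trials) > n_expected:
        trials = trials[ANTISACCADE_PRACTICE_TRIALS:]
    if len(trials) < n_expected:
        warnings.warn(
            f"{task} session truncated: {len(trials)} of {n_expected} trials parsed"
        )
    return trials


def _attach_events(trial: Trial, saccades: list[SaccadeEvent]) -> None:
    lo = trial.target_onset_ms - FIXATION_WINDOW_MS
    trial.events = [
        ev for ev in saccades if lo <= ev.onset_ms <= trial.target_offset_ms
    ]


def validate_trial(
    trial: Trial,
    recording: GazeRecording,
    saccades: list[SaccadeEvent],
    blinks: list[tuple[float, float]],
) -> Trial:
    """Apply the validity rules; sets ``valid`` and ``invalid_reason``.

    Reasons: late_fixation, off_fixation, saccade_in_fixation,
    blink_in_fixation, anticipatory, initial_saccade_too_late, no_saccade.
    """
    _attach_events(trial, saccades)
    t0 = trial.target_onset_ms
    win_lo = t0 - FIXATION_WINDOW_MS

    for lo, hi in blinks:
        if lo <= t0 and hi >= win_lo:
            trial.valid, trial.invalid_reason = False, "blink_in_fixation"
            return trial
    for ev in saccades:
        if ev.onset_ms <= t0 and ev.offset_ms >= win_lo:
            if ev.offset_ms > win_lo and ev.onset_ms < win_lo:
                trial.valid, trial.invalid_reason = False, "late_fixation"
            else:
                trial.valid, trial.invalid_reason = False, "saccade_in_fixation"
            return trial

    t = recording.times
    sel = (t >= win_lo) & (t <= t0)
    x = recording.samples["x_deg"].to_numpy(dtype=float)[sel]
    y = recording.samples["y_deg"].to_numpy(dtype=float)[sel]
    if len(x) and float(np.hypot(x, y).mean()) > FIXATION_OFF_MAX_DEG:
        trial.valid, trial.invalid_reason = False, "off_fixation"
        return trial

    initial = next((ev for ev in trial.events if ev.onset_ms >= t0), None)
    if initial is None:
        trial.valid, trial.invalid_reason = False, "no_saccade"
        return trial
    latency = initial.onset_ms - t0
    if latency < LATENCY_MIN_MS:
        trial.valid, trial.invalid_reason = False, "anticipatory"
        return trial
    if initial.offset_ms > trial.target_offset_ms:
        trial.valid, trial.invalid_reason = False, "initial_saccade_too_late"
        return trial
    trial.valid, trial.invalid_reason = True, ""
    return trial


def score_saccade_trial(trial: Trial, task: str) -> TrialMetrics:
    """Score one valid trial; raises when the trial is invalid.

    All positions are mirrored to a canonical rightward frame (target at
    +9.63 deg) so one code path scores both sides.  In the canonical
    frame the required landing position is +9.63 for prosaccades and
    -9.63 (the mirror position) for antisaccades.
    """
    if not trial.valid:
        raise ValueError(f"trial {trial.index} is invalid ({trial.invalid_reason})")
    t0 = trial.target_onset_ms
    initial = next(ev for ev in trial.events if ev.onset_ms >= t0)
    mirror = np.sign(trial.target_x)  # canonicalizing factor
    dx = (initial.end_x - initial.start_x) * mirror
    required_x = TARGET_ECCENTRICITY if task == "prosaccade" else -TARGET_ECCENTRICITY
    toward_target = dx > 0
    direction_correct = toward_target if task == "prosaccade" else not toward_target

    landing = initial.end_x * mirror
    corrected = None
    if task == "antisaccade" and not direction_correct:
        corrected = False
        for ev in trial.events:
            if ev.onset_ms <= initial.offset_ms or ev.onset_ms > trial.target_offset_ms:
                continue
            d = (ev.end_x - ev.start_x) * mirror
            if d < 0 and ev.end_x * mirror <= 0.0:  # toward mirror, crossing midline
                corrected = True
                break

    return TrialMetrics(
        index=trial.index,
        latency_ms=initial.onset_ms - t0,
        amplitude_gain=initial.amplitude / TARGET_ECCENTRICITY * 100.0,
        spatial_error=abs(landing - required_x) / TARGET_ECCENTRICITY * 100.0,
        peak_velocity=initial.peak_velocity,
        adjusted_peak_velocity=initial.peak_velocity / initial.amplitude,
        direction_correct=bool(direction_correct),
        corrected=corrected,
    )


def summarize_saccade_task(
    recording: GazeRecording, task: str
) -> tuple[list[Trial], list[TrialMetrics]]:
    """Parse, validate and score every trial of a saccade-task session."""
    kin = compute_kinematics(recording)
    saccades = detect_saccades(recording, kin)
    blinks = detect_blinks(recording)
    trials = parse_trials(recording, task)
    metrics = []
    for trial in trials:
        validate_trial(trial, recording, saccades, blinks)
        if trial.valid:
            metrics.append(score_saccade_trial(trial, task))
    return trials, metrics


@dataclass
class SubjectOculomotorSummary:
    """The 16 per-subject eye-movement outcomes plus validity counts.

    Absent outcomes (insufficient qualifying trials) are NaN, never zero.
    """

    fixation_spatial_error: float = float("nan")
    fixation_saccade_rate: float = float("nan")
    fixation_blink_rate: float = float("nan")
    spem_velocity_gain: float = float("nan")
    spem_saccade_rate: float = float("nan")
    prosaccade_latency: float = float("nan")
    prosaccade_amplitude_gain: float = float("nan")
    prosaccade_spatial_error: float = float("nan")
    prosaccade_peak_velocity: float = float("nan")
    prosaccade_adjusted_peak_velocity: float = float("nan")
    antisaccade_latency: float = float("nan")
    antisaccade_amplitude_gain: float = float("nan")
    antisaccade_spatial_error: float = float("nan")
    antisaccade_peak_velocity: float = float("nan")
    antisaccade_adjusted_peak_velocity: float = float("nan")
    antisaccade_costs: float = float("nan")
    antisaccade_error_rate: float = float("nan")
    antisaccade_correction_rate: float = float("nan")
    n_valid_pro: int = 0
    n_valid_correct_pro: int = 0
    n_valid_anti: int = 0
    n_valid_correct_anti: int = 0
    n_direction_errors: int = 0

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def _mean_metrics(metrics: list[TrialMetrics], prefix: str, out: dict) -> None:
    out[f"{prefix}_latency"] = float(np.mean([m.latency_ms for m in metrics]))
    out[f"{prefix}_amplitude_gain"] = float(np.mean([m.amplitude_gain for m in metrics]))
    out[f"{prefix}_spatial_error"] = float(np.mean([m.spatial_error for m in metrics]))
    out[f"{prefix}_peak_velocity"] = float(np.mean([m.peak_velocity for m in metrics]))
    out[f"{prefix}_adjusted_peak_velocity"] = float(
        np.mean([m.adjusted_peak_velocity for m in metrics])
    )


def aggregate_subject(
    pro_metrics: list[TrialMetrics] | None = None,
    anti_metrics: list[TrialMetrics] | None = None,
    fixation: dict | None = None,
    spem: dict | None = None,
) -> SubjectOculomotorSummary:
    """Combine per-task metrics into the subject-level outcome summary."""
    out: dict = {}
    if fixation is not None:
        out["fixation_spatial_error"] = fixation["spatial_error"]
        out["fixation_saccade_rate"] = fixation["saccade_rate"]
        out["fixation_blink_rate"] = fixation["blink_rate"]
    if spem is not None:
        out["spem_velocity_gain"] = spem["velocity_gain"]
        out["spem_saccade_rate"] = spem["saccade_rate"]

    pro_metrics = pro_metrics or []
    anti_metrics = anti_metrics or []
    pro_correct = [m for m in pro_metrics if m.direction_correct]
    anti_correct = [m for m in anti_metrics if m.direction_correct]
    out["n_valid_pro"] = len(pro_metrics)
    out["n_valid_correct_pro"] = len(pro_correct)
    out["n_valid_anti"] = len(anti_metrics)
    out["n_valid_correct_anti"] = len(anti_correct)

    if len(pro_correct) >= MIN_VALID_CORRECT_TRIALS:
        _mean_metrics(pro_correct, "prosaccade", out)
    if len(anti_correct) >= MIN_VALID_CORRECT_TRIALS:
        _mean_metrics(anti_correct, "antisaccade", out)
    if "prosaccade_latency" in out and "antisaccade_latency" in out:
        out["antisaccade_costs"] = out["antisaccade_latency"] - out["prosaccade_latency"]

    errors = [m for m in anti_metrics if not m.direction_correct]
    out["n_direction_errors"] = len(errors)
    if anti_metrics:
        out["antisaccade_error_rate"] = len(errors) / len(anti_metrics) * 100.0
    if len(errors) >= MIN_DIRECTION_ERRORS:
        n_corrected = sum(1 for m in errors if m.corrected)
        if n_corrected >= 1:
            out["antisaccade_correction_rate"] = n_corrected / len(errors) * 100.0
    return SubjectOculomotorSummary(**out)
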