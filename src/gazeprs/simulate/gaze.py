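"""Synthetic gaze recordings for fixation, pursuit and saccade tasks.

The simulator emulates 1000 Hz video-oculography traces with the task
geometry of a population-cohort eye-movement battery:

* fixation: target at the centre for 5 s, then at each of four eccentric
  positions (+-9.63 deg on one axis) for 10 s, returning to the centre
  after each of the first three, so the centre is fixated four times;
* smooth pursuit: after 1 s at the centre the target moves sinusoidally
  between +-9.63 deg at 0.5 Hz for ten full cycles (21 s task);
* prosaccade / antisaccade: 30 trials (plus six antisaccade practice
  trials); the target holds the centre for a uniform 1-2 s, steps to
  x = +-9.63 deg (15 times per side, shuffled) for 1 s, and returns.

Saccades are synthesized with a raised-cosine velocity profile whose peak
follows the main-sequence law V_peak = V_max*(1 - exp(-A/c)); latencies
are truncated normal (floor 80 ms).  Antisaccade trials contain direction
errors with a configurable probability, each followed by a midline-crossing
corrective saccade with the correction probability.  Blinks freeze the
trace and set the blink flag; they are scheduled away from planned
saccades so ground truth stays exact.  Every synthesized event is logged
with onset, amplitude, direction and trial labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gazeprs.oculomotor.recording import GazeRecording

__all__ = [
    "GazeSimConfig",
    "SubjectParams",
    "TaskSpec",
    "make_task",
    "simulate_gaze_session",
    "SimulatedSession",
]

ECCENTRICITY = 9.63  # deg
PURSUIT_FREQ = 0.5  # Hz
PURSUIT_CYCLES = 10
N_TRIALS = 30
N_PRACTICE = 6
TARGET_HOLD_MS = 1000.0


@dataclass(frozen=True)
class TaskSpec:
    """Name and geometry of one oculomotor task."""

    name: str  # fixation | spem | prosaccade | antisaccade
    eccentricity: float = ECCENTRICITY
    n_trials: int = N_TRIALS
    n_practice: int = 0


def make_task(name: str) -> TaskSpec:
    if name == "antisaccade":
        return TaskSpec(name=name, n_practice=N_PRACTICE)
    if name in ("fixation", "spem", "prosaccade"):
        return TaskSpec(name=name)
    raise ValueError(f"unknown task {name!r}")


@dataclass(frozen=True)
class GazeSimConfig:
    """Recording-level simulation parameters."""

    sampling_rate: float = 1000.0  # Hz
    noise_sd: float = 0.05  # deg per axis
    blink_rate: float = 2.0  # events per minute
    latency_mean: float = 200.0  # ms
    latency_sd: float = 30.0  # ms
    direction_error_prob: float = 0.3
    correction_prob: float = 0.95
    main_sequence: tuple[float, float] = (500.0, 7.5)  # V_max deg/s, constant deg
    latency_floor: float = 80.0  # ms; synthetic latencies never go below
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for p in (self.direction_error_prob, self.correction_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject oculomotor characteristics."""

    saccade_gain: float = 0.95  # mean amplitude gain, proportion
    saccade_gain_sd: float = 0.04  # trial-to-trial gain spread
    pursuit_gain: float = 0.85
    correction_delay_mean: float = 180.0  # ms after the erroneous saccade
    correction_delay_sd: float = 40.0


@dataclass
class SimulatedSession:
    """A synthetic recording plus its ground-truth event and trial logs."""

    recording: GazeRecording
    events: pd.DataFrame  # trial, kind, onset_ms, amplitude, direction, ...
    trials: pd.DataFrame | None = None  # per-trial ground-truth labels


def _peak_velocity(amplitude: float, main_sequence: tuple[float, float]) -> float:
    v_max, c = main_sequence
    return v_max * (1.0 - np.exp(-amplitude / c))


def _truncated_latency(rng, mean, sd, floor) -> float:
    for _ in range(1000):
        lat = rng.normal(mean, sd)
        if lat >= floor:
            return float(lat)
    return float(floor)


class _TraceBuilder:
    """Accumulates hold segments and raised-cosine saccades on a time grid."""

    def __init__(self, duration_ms: float, config: GazeSimConfig):
        self.cfg = config
        self.dt = 1000.0 / config.sampling_rate
        self.n = int(round(duration_ms / self.dt))
        self.t = np.arange(self.n) * self.dt
        self.x = np.zeros(self.n)
        self.y = np.zeros(self.n)
        self.cursor = 0  # next sample to fill
        self.pos = (0.0, 0.0)
        self.events: list[dict] = []
        self.saccade_windows: list[tuple[float, float]] = []

    def hold_until(self, time_ms: float) -> None:
        end = min(self.n, int(round(time_ms / self.dt)))
        if end > self.cursor:
            self.x[self.cursor : end] = self.pos[0]
            self.y[self.cursor : end] = self.pos[1]
            self.cursor = end

    def saccade(self, onset_ms: float, target: tuple[float, float], **labels) -> dict:
        """Insert a saccade starting at ``onset_ms`` landing on ``target``."""
        self.hold_until(onset_ms)
        x0, y0 = self.pos
        dx, dy = target[0] - x0, target[1] - y0
        amplitude = float(np.hypot(dx, dy))
        if amplitude < 1e-9:
            return {}
        vp = _peak_velocity(amplitude, self.cfg.main_sequence)
        dur_ms = 2.0 * amplitude / vp * 1000.0
        n_samp = max(2, int(round(dur_ms / self.dt)))
        start = self.cursor
        end = min(self.n, start + n_samp)
        # raised-cosine velocity -> position s(t) = A*(u - sin(2*pi*u)/(2*pi))
        u = np.arange(1, end - start + 1) / n_samp
        s = u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)
        self.x[start:end] = x0 + dx * s[: end - start]
        self.y[start:end] = y0 + dy * s[: end - start]
        self.cursor = end
        self.pos = (x0 + dx, y0 + dy)
        onset = start * self.dt
        offset = (end - 1) * self.dt
        event = {
            "onset_ms": onset,
            "offset_ms": offset,
            "amplitude": amplitude,
            "direction": int(np.sign(dx)) if dx else 0,
            "peak_velocity": vp,
            **labels,
        }
        self.events.append(event)
        self.saccade_windows.append((onset - 100.0, offset + 100.0))
        return event

    def finish(self, rng, blink_rate_per_min: float, noise_sd: float):
        self.hold_until(self.n * self.dt)
        blink = np.zeros(self.n, dtype=int)
        duration_min = self.n * self.dt / 60000.0
        n_blinks = rng.poisson(blink_rate_per_min * duration_min)
        placed = 0
        for _ in range(200):
            if placed >= n_blinks:
                break
            t0 = rng.uniform(0, self.n * self.dt - 200.0)
            dur = rng.uniform(80.0, 150.0)
            if any(lo - dur < t0 < hi for lo, hi in self.saccade_windows):
                continue
            i0 = int(t0 / self.dt)
            i1 = min(self.n, int((t0 + dur) / self.dt))
            blink[i0:i1] = 1
            # tracker freezes at the last pre-blink position
            if i0 > 0:
                self.x[i0:i1] = self.x[i0 - 1]
                self.y[i0:i1] = self.y[i0 - 1]
            placed += 1
        if noise_sd > 0:
            ok = blink == 0
            self.x[ok] += rng.normal(0, noise_sd, ok.sum())
            self.y[ok] += rng.normal(0, noise_sd, ok.sum())
        return blink


def simulate_gaze_session(
    task: TaskSpec | str,
    config: GazeSimConfig | None = None,
    subject: SubjectParams | None = None,
    seed: int | None = None,
) -> SimulatedSession:
    """Synthesize one task run; returns recording plus ground-truth logs."""
    if isinstance(task, str):
        task = make_task(task)
    cfg = config or GazeSimConfig()
    sp = subject or SubjectParams()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if task.name == "fixation":
        return _simulate_fixation(task, cfg, sp, rng)
    if task.name == "spem":
        return _simulate_pursuit(task, cfg, sp, rng)
    if task.name in ("prosaccade", "antisaccade"):
        return _simulate_saccade_task(task, cfg, sp, rng)
    raise ValueError(f"unknown task {task.name!r}")


def _simulate_fixation(task, cfg, sp, rng) -> SimulatedSession:
    ecc = task.eccentricity
    eccentrics = [(0.0, ecc), (0.0, -ecc), (-ecc, 0.0), (ecc, 0.0)]
    rng.shuffle(eccentrics)
    segments: list[tuple[float, tuple[float, float]]] = []
    for i, pos in enumerate(eccentrics):
        segments.append((5000.0, (0.0, 0.0)))
        segments.append((10000.0, pos))
    total = sum(d for d, _ in segments)
    tb = _TraceBuilder(total, cfg)
    messages = []
    t_cursor = 0.0
    for dur, pos in segments:
        messages.append({"time_ms": t_cursor, "event": f"TARGET_ON {pos[0]:g} {pos[1]:g}"})
        if pos != tb.pos:
            lat = _truncated_latency(rng, cfg.latency_mean, cfg.latency_sd, cfg.latency_floor)
            tb.saccade(t_cursor + lat, pos, trial=-1, kind="refix")
        t_cursor += dur
        tb.hold_until(t_cursor)
    blink = tb.finish(rng, cfg.blink_rate, cfg.noise_sd)
    rec = _to_recording(tb, blink, messages, cfg)
    return SimulatedSession(rec, pd.DataFrame(tb.events))


def _simulate_pursuit(task, cfg, sp, rng) -> SimulatedSession:
    lead = 1000.0
    move = PURSUIT_CYCLES / PURSUIT_FREQ * 1000.0
    tb = _TraceBuilder(lead + move, cfg)
    tb.hold_until(lead)
    omega = 2.0 * np.pi * PURSUIT_FREQ
    sel = tb.t >= lead
    ts = (tb.t[sel] - lead) / 1000.0
    tb.x[sel] = sp.pursuit_gain * task.eccentricity * np.sin(omega * ts)
    tb.cursor = tb.n
    tb.pos = (float(tb.x[-1]), 0.0)
    messages = [
        {"time_ms": 0.0, "event": "TARGET_ON 0 0"},
        {"time_ms": lead, "event": f"PURSUIT_START {task.eccentricity:g} {PURSUIT_FREQ:g}"},
    ]
    blink = tb.finish(rng, cfg.blink_rate, cfg.noise_sd)
    rec = _to_recording(tb, blink, messages, cfg)
    truth = pd.DataFrame([{"kind": "pursuit", "velocity_gain": sp.pursuit_gain * 100.0}])
    return SimulatedSession(rec, pd.DataFrame(tb.events), truth)


def _simulate_saccade_task(task, cfg, sp, rng) -> SimulatedSession:
    n_total = task.n_trials + task.n_practice
    sides = np.array([1] * (task.n_trials // 2) + [-1] * (task.n_trials - task.n_trials // 2))
    rng.shuffle(sides)
    practice_sides = rng.choice([-1, 1], size=task.n_practice)
    all_sides = np.concatenate([practice_sides, sides])
    holds = rng.uniform(1000.0, 2000.0, size=n_total)
    total = float(np.sum(holds) + n_total * TARGET_HOLD_MS) + 500.0
    tb = _TraceBuilder(total, cfg)
    messages = []
    trial_rows = []
    anti = task.name == "antisaccade"
    t_cursor = 0.0
    for k in range(n_total):
        idx = k + 1
        side = int(all_sides[k])
        tx = side * task.eccentricity
        messages.append({"time_ms": t_cursor, "event": f"TRIAL_START {idx}"})
        messages.append({"time_ms": t_cursor, "event": "TARGET_ON 0 0"})
        onset = t_cursor + holds[k]
        messages.append({"time_ms": onset, "event": f"TARGET_ON {tx:g} 0"})
        offset = onset + TARGET_HOLD_MS
        lat = _truncated_latency(rng, cfg.latency_mean, cfg.latency_sd, cfg.latency_floor)
        gain = max(0.2, rng.normal(sp.saccade_gain, sp.saccade_gain_sd))
        is_error = False
        corrected: bool | None = None
        if anti:
            is_error = bool(rng.random() < cfg.direction_error_prob)
            goal = tx * gain if is_error else -tx * gain
        else:
            goal = tx * gain
        ev = tb.saccade(onset + lat, (goal, 0.0), trial=idx, kind="initial")
        if anti and is_error:
            corrected = bool(rng.random() < cfg.correction_prob)
            if corrected:
                delay = max(
                    80.0, rng.normal(sp.correction_delay_mean, sp.correction_delay_sd)
                )
                cgain = max(0.2, rng.normal(sp.saccade_gain, sp.saccade_gain_sd))
                tb.saccade(
                    ev["offset_ms"] + delay, (-tx * cgain, 0.0), trial=idx, kind="corrective"
                )
        # return to centre for the next trial
        ret_lat = _truncated_latency(rng, cfg.latency_mean, cfg.latency_sd, cfg.latency_floor)
        tb.saccade(offset + ret_lat, (0.0, 0.0), trial=idx, kind="return")
        messages.append({"time_ms": offset, "event": "TARGET_ON 0 0"})
        messages.append({"time_ms": offset + 400.0, "event": f"TRIAL_END {idx}"})
        trial_rows.append(
            {
                "trial": idx,
                "practice": k < task.n_practice,
                "side": "right" if side > 0 else "left",
                "target_onset_ms": onset,
                "latency_ms": lat,
                "amplitude": abs(goal),
                "direction_error": is_error,
                "corrected": corrected,
            }
        )
        # next trial's centre hold starts when the target returns to centre
        t_cursor = offset
    blink = tb.finish(rng, cfg.blink_rate, cfg.noise_sd)
    rec = _to_recording(tb, blink, messages, cfg)
    return SimulatedSession(rec, pd.DataFrame(tb.events), pd.DataFrame(trial_rows))


def _to_recording(tb: _TraceBuilder, blink, messages, cfg) -> GazeRecording:
    samples = pd.DataFrame(
        {"time_ms": tb.t, "x_deg": tb.x, "y_deg": tb.y, "blink": blink}
    )
    msg = pd.DataFrame(messages, columns=["time_ms", "event"])
    return GazeRecording(samples=samples, messages=msg, sampling_rate=cfg.sampling_rate)
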