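"""Fixation-stability and smooth-pursuit outcome measures.

Fixation task: the target sits at the centre, then at four eccentric
positions with centre returns; fixation stability is summarized as the
root-mean-square Euclidean distance between gaze and the current target
over fixation periods (>= 100 ms without blinks or saccades, gaze directed
toward the target), together with saccade and blink rates per second.

Smooth-pursuit task: the target moves sinusoidally; samples with speed
< 30 deg/s sustained for >= 50 ms are classified as pursuit.  Velocity gain
is the ratio of mean horizontal eye velocity to mean target velocity over
pursuit samples within the middle two temporal quarters of each half-cycle,
averaged across half-cycles, in percent.
"""

from __future__ import annotations

import numpy as np

from gazeprs.oculomotor.events import compute_kinematics, detect_blinks, detect_saccades
from gazeprs.oculomotor.recording import GazeRecording

__all__ = ["summarize_fixation_task", "summarize_spem_task"]

FIXATION_MIN_MS = 100.0
FIXATION_TOLERANCE_DEG = 3.0  # gaze counted as on-target within this distance
SPEM_VELOCITY_MAX = 30.0  # deg/s
SPEM_MIN_DURATION_MS = 50.0


def _event_free_mask(times: np.ndarray, saccades, blinks) -> np.ndarray:
    free = np.ones(len(times), dtype=bool)
    for ev in saccades:
        free &= ~((times >= ev.onset_ms) & (times <= ev.offset_ms))
    for lo, hi in blinks:
        free &= ~((times >= lo) & (times <= hi))
    return free


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    edges = np.diff(mask.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


def summarize_fixation_task(recording: GazeRecording) -> dict:
    """Fixation spatial RMSE (deg), saccade rate (/s) and blink rate (/s).

    Returns a dict with keys ``spatial_error``, ``saccade_rate``,
    ``blink_rate`` and ``n_fixation_periods``; the spatial error is NaN
    when no qualifying fixation period exists.
    """
    targets = recording.target_positions()
    if targets.empty:
        raise ValueError("fixation recording has no TARGET_ON messages")
    t = recording.times
    saccades = detect_saccades(recording)
    blinks = detect_blinks(recording)
    free = _event_free_mask(t, saccades, blinks)

    x = recording.samples["x_deg"].to_numpy(dtype=float)
    y = recording.samples["y_deg"].to_numpy(dtype=float)
    # step targets: hold previous value, no ramp between positions
    idx = np.searchsorted(targets["time_ms"].to_numpy(), t, side="right") - 1
    idx = np.clip(idx, 0, len(targets) - 1)
    tx = targets["x"].to_numpy()[idx]
    ty = targets["y"].to_numpy()[idx]

    # fixation periods cannot span a target step: split event-free runs at
    # epoch boundaries so the pre-saccade lag after a step (gaze still on
    # the old target) is judged against the new target and excluded
    boundary = np.zeros(len(t), dtype=bool)
    b_idx = np.searchsorted(t, targets["time_ms"].to_numpy()[1:])
    boundary[b_idx[b_idx < len(t)]] = True
    free = free & ~boundary
    dt_ms = 1000.0 / recording.sampling_rate
    sq_sum, n_fix_samples, n_periods = 0.0, 0, 0
    dist = np.hypot(x - tx, y - ty)
    for s, e in _runs(free):
        if (e - s + 1) * dt_ms < FIXATION_MIN_MS:
            continue
        seg = slice(s, e + 1)
        if np.mean(dist[seg]) > FIXATION_TOLERANCE_DEG:
            continue  # gaze not directed toward the target
        sq_sum += float(np.sum(dist[seg] ** 2))
        n_fix_samples += e - s + 1
        n_periods += 1
    duration_s = recording.duration_ms / 1000.0
    rmse = float(np.sqrt(sq_sum / n_fix_samples)) if n_fix_samples else float("nan")
    return {
        "spatial_error": rmse,
        "saccade_rate": len(saccades) / duration_s,
        "blink_rate": len(blinks) / duration_s,
        "n_fixation_periods": n_periods,
    }


def summarize_spem_task(recording: GazeRecording) -> dict:
    """Pursuit velocity gain (%) and saccade rate (/s).

    The PURSUIT_START message carries the amplitude (deg) and frequency
    (Hz) of the sinusoidal target.  Gain is NaN when fewer than one full
    half-cycle is recorded.
    """
    start = None
    for _, m in recording.messages.iterrows():
        parts = str(m["event"]).split()
        if parts and parts[0] == "PURSUIT_START":
            start = (float(m["time_ms"]), float(parts[1]), float(parts[2]))
            break
    if start is None:
        raise ValueError("pursuit recording has no PURSUIT_START message")
    t0, amp, freq = start

    kin = compute_kinematics(recording)
    saccades = detect_saccades(recording, kin)
    t = recording.times
    dt_ms = 1000.0 / recording.sampling_rate

    # pursuit classification: speed < 30 deg/s sustained for >= 50 ms
    slow = kin.valid & (kin.speed < SPEM_VELOCITY_MAX)
    spem = np.zeros_like(slow)
    for s, e in _runs(slow):
        if (e - s + 1) * dt_ms >= SPEM_MIN_DURATION_MS:
            spem[s : e + 1] = True

    # a half-cycle of target motion (left-to-right or right-to-left) runs
    # between successive position extremes, the first extreme sitting a
    # quarter period after motion onset; its middle two quarters straddle
    # the velocity peak, keeping the gain ratio well away from 0/0
    half_ms = 1000.0 / (2.0 * freq)
    first_extreme = t0 + 0.5 * half_ms
    t_end = t[-1]
    n_half = int((t_end - first_extreme) // half_ms)
    if n_half < 1:
        return {"velocity_gain": float("nan"), "saccade_rate": len(saccades) / (recording.duration_ms / 1000.0), "n_half_cycles": 0}

    omega = 2.0 * np.pi * freq
    target_v = amp * omega * np.cos(omega * (t - t0) / 1000.0)  # deg/s
    gains = []
    for i in range(n_half):
        lo = first_extreme + i * half_ms + 0.25 * half_ms
        hi = first_extreme + i * half_ms + 0.75 * half_ms
        sel = (t >= lo) & (t < hi) & spem
        if sel.sum() < 2:
            continue
        tv = float(np.mean(target_v[sel]))
        if abs(tv) < 1e-9:
            continue
        gains.append(float(np.mean(kin.vx[sel])) / tv)
    gain = 100.0 * float(np.mean(gains)) if gains else float("nan")
    return {
        "velocity_gain": gain,
        "saccade_rate": len(saccades) / (recording.duration_ms / 1000.0),
        "n_half_cycles": len(gains),
    }
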