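"""Gaze recording container and text importers.

Coordinates are degrees of visual angle with the screen centre as origin,
rightward/upward positive.  The native dialect is a pair of TSV files: a
sample file with columns ``time_ms, x_deg, y_deg, blink`` and a message
file with columns ``time_ms, event`` (``TARGET_ON x y``, ``TRIAL_START k``,
``TRIAL_END k``, ``PURSUIT_START amp freq``).  A minimal importer for
EyeLink ASC-style text (SAMPLE lines plus MSG lines) maps to the same
container.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GazeRecording", "read_gaze_tsv", "read_asc"]


@dataclass
class GazeRecording:
    """Time-stamped gaze samples plus the task/message log for one run."""

    samples: pd.DataFrame  # time_ms, x_deg, y_deg, blink
    messages: pd.DataFrame  # time_ms, event
    sampling_rate: float

    def __post_init__(self) -> None:
        t = self.samples["time_ms"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("recording needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("sample times must be strictly increasing")
        nominal = 1000.0 / self.sampling_rate
        if np.any(np.abs(dt - nominal) > 0.01 * nominal):
            raise ValueError("sampling interval varies by more than 1%")
        blink = self.samples["blink"].to_numpy() > 0
        xy = self.samples[["x_deg", "y_deg"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy[~blink])):
            raise ValueError("non-blink samples must have finite coordinates")

    @property
    def times(self) -> np.ndarray:
        return self.samples["time_ms"].to_numpy(dtype=float)

    @property
    def duration_ms(self) -> float:
        t = self.times
        return float(t[-1] - t[0] + 1000.0 / self.sampling_rate)

    def to_tsv(self, gaze_path, message_path) -> None:
        out = self.samples.copy()
        out["blink"] = out["blink"].astype(int)
        out.to_csv(gaze_path, sep="\t", index=False, float_format="%.4f")
        self.messages.to_csv(message_path, sep="\t", index=False)

    def target_positions(self) -> pd.DataFrame:
        """TARGET_ON messages parsed into (time_ms, x, y) rows."""
        rows = []
        for _, m in self.messages.iterrows():
            parts = str(m["event"]).split()
            if parts and parts[0] == "TARGET_ON":
                rows.append(
                    {"time_ms": float(m["time_ms"]), "x": float(parts[1]), "y": float(parts[2])}
                )
        return pd.DataFrame(rows, columns=["time_ms", "x", "y"])


def _infer_rate(times: np.ndarray) -> float:
    return 1000.0 / float(np.median(np.diff(times)))


def read_gaze_tsv(gaze_path, message_path) -> GazeRecording:
    samples = pd.read_csv(gaze_path, sep="\t")
    messages = pd.read_csv(message_path, sep="\t")
    required = {"time_ms", "x_deg", "y_deg", "blink"}
    if not required.issubset(samples.columns):
        raise ValueError(f"gaze TSV must have columns {sorted(required)}")
    rate = _infer_rate(samples["time_ms"].to_numpy(dtype=float))
    return GazeRecording(samples=samples, messages=messages, sampling_rate=rate)


def read_asc(path) -> GazeRecording:
    """Minimal EyeLink ASC-style text importer.

    Sample lines are ``<time> <x> <y> <pupil> ...`` with ``.`` for missing
    (blink) coordinates; message lines are ``MSG <time> <text>``.  Other
    event lines (SSACC, EBLINK, ...) are ignored — events are re-detected
    from the samples.
    """
    srows, mrows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "MSG" and len(parts) >= 3:
                mrows.append({"time_ms": float(parts[1]), "event": " ".join(parts[2:])})
            elif parts[0][0].isdigit():
                t = float(parts[0])
                if len(parts) >= 3 and parts[1] != "." and parts[2] != ".":
                    srows.append(
                        {"time_ms": t, "x_deg": float(parts[1]), "y_deg": float(parts[2]), "blink": 0}
                    )
                else:
                    srows.append({"time_ms": t, "x_deg": np.nan, "y_deg": np.nan, "blink": 1})
    samples = pd.DataFrame(srows, columns=["time_ms", "x_deg", "y_deg", "blink"])
    if samples.empty:
        raise ValueError(f"no samples found in {path}")
    samples.loc[samples["blink"] == 1, ["x_deg", "y_deg"]] = 0.0
    messages = pd.DataFrame(mrows, columns=["time_ms", "event"])
    rate = _infer_rate(samples["time_ms"].to_numpy(dtype=float))
    return GazeRecording(samples=samples, messages=messages, sampling_rate=rate)
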