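"""Core containers: timestamped angular traces and recording sessions.

Angles are degrees throughout. Sign convention: negative yaw = left,
positive yaw = right; negative pitch = down, positive pitch = up.
Eye traces live in the head frame, head and gaze traces in the world frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

EFFECTORS = ("eye", "head", "gaze")
FRAMES = ("head_frame", "world_frame")

#: frame each effector's trace is expressed in
EXPECTED_FRAME = {"eye": "head_frame", "head": "world_frame", "gaze": "world_frame"}


@dataclass
class EffectorTrace:
    """Yaw/pitch time series for one effector in a declared frame.

    Parameters
    ----------
    effector : {"eye", "head", "gaze"}
    frame : {"head_frame", "world_frame"}
    t : array of sample times in seconds, non-decreasing
    yaw, pitch : arrays of angles in degrees
    roll : optional array of roll angles (head only, ignored by analyses)
    valid : boolean array; invalid samples are tracker dropouts/blinks
    nominal_rate : nominal sampling rate in Hz (120 by default)
    """

    effector: str
    frame: str
    t: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    roll: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None
    nominal_rate: float = 120.0

    def __post_init__(self) -> None:
        if self.effector not in EFFECTORS:
            raise ValueError(f"unknown effector {self.effector!r}; expected one of {EFFECTORS}")
        if self.frame not in FRAMES:
            raise ValueError(f"unknown frame {self.frame!r}; expected one of {FRAMES}")
        if self.frame != EXPECTED_FRAME[self.effector]:
            raise ValueError(
                f"{self.effector} traces must be in {EXPECTED_FRAME[self.effector]}, "
                f"got {self.frame}"
            )
        self.t = np.asarray(self.t, dtype=float)
        self.yaw = np.asarray(self.yaw, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        n = self.t.size
        if self.yaw.size != n or self.pitch.size != n:
            raise ValueError("t, yaw and pitch must have equal length")
        if self.roll is not None:
            self.roll = np.asarray(self.roll, dtype=float)
            if self.roll.size != n:
                raise ValueError("roll must match trace length")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.size != n:
                raise ValueError("valid must match trace length")
        if n > 1 and np.any(np.diff(self.t) < 0):
            idx = int(np.argmax(np.diff(self.t) < 0))
            raise ValueError(f"time must be non-decreasing; first violation at index {idx + 1}")

    def __len__(self) -> int:
        return self.t.size

    def copy(self) -> "EffectorTrace":
        return replace(
            self,
            t=self.t.copy(),
            yaw=self.yaw.copy(),
            pitch=self.pitch.copy(),
            roll=None if self.roll is None else self.roll.copy(),
            valid=self.valid.copy(),
        )

    def take(self, index: np.ndarray) -> "EffectorTrace":
        """Sub-trace at the given sample indices (order preserved)."""
        return replace(
            self,
            t=self.t[index],
            yaw=self.yaw[index],
            pitch=self.pitch[index],
            roll=None if self.roll is None else self.roll[index],
            valid=self.valid[index],
        )

    def angles(self) -> np.ndarray:
        """(n, 2) array of (yaw, pitch) pairs."""
        return np.column_stack([self.yaw, self.pitch])


@dataclass
class Session:
    """One participant x condition recording.

    Holds synchronized eye (head frame) and head (world frame) traces, the
    visual-search trial windows (half-open [start, end) in seconds), and
    participant metadata. Simulated sessions additionally carry the latent
    ground truth used to generate them.
    """

    participant: str
    condition: str  # "optimal" | "degraded"
    group: str  # "lower" | "higher"
    eye: EffectorTrace
    head: EffectorTrace
    trial_windows: list = field(default_factory=list)
    gaze: Optional[EffectorTrace] = None
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.eye.effector != "eye":
            raise ValueError("Session.eye must be an eye trace")
        if self.head.effector != "head":
            raise ValueError("Session.head must be a head trace")
        for a, b in zip(self.trial_windows, self.trial_windows[1:]):
            if a[1] > b[0]:
                raise ValueError("trial windows must be sorted and non-overlapping")

    @property
    def duration_s(self) -> float:
        return float(self.eye.t[-1] - self.eye.t[0]) if len(self.eye) else 0.0
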