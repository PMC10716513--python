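"""Time-indexed binocular eye-tracking samples for a single trial.

All gaze coordinates are screen-centered visual degrees (rightward/upward
positive), pupil diameters are millimetres, and time is seconds from trial
start.  Missing samples are NaN; the TSV readers/writers translate NaN to an
explicit ``NA`` token.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

GAZE_CHANNELS = ("lx", "ly", "rx", "ry")
PUPIL_CHANNELS = ("lp", "rp")
CHANNELS = GAZE_CHANNELS + PUPIL_CHANNELS


@dataclass
class EyeSampleSeries:
    """One trial's binocular samples plus its event markers.

    Event markers satisfy ``sound_onset_s < visual_onset_s < visual_offset_s``;
    for silent trials ``sound_onset_s`` is the equivalent timeline marker (the
    moment a sound would have started).
    """

    t: np.ndarray
    lx: np.ndarray
    ly: np.ndarray
    rx: np.ndarray
    ry: np.ndarray
    lp: np.ndarray
    rp: np.ndarray
    sound_onset_s: float
    visual_onset_s: float
    visual_offset_s: float
    infant_id: str = ""
    trial_index: int = 0
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"channel {name!r} has shape {arr.shape}, "
                                 f"expected {self.t.shape}")
            setattr(self, name, arr)
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def fs(self) -> float:
        """Nominal sampling rate estimated from the median sample period."""
        if self.t.size < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(self.t)))

    def copy(self) -> "EyeSampleSeries":
        return replace(
            self,
            t=self.t.copy(),
            lx=self.lx.copy(), ly=self.ly.copy(),
            rx=self.rx.copy(), ry=self.ry.copy(),
            lp=self.lp.copy(), rp=self.rp.copy(),
            flags=dict(self.flags),
        )

    def window_mask(self, start_s: float, end_s: float) -> np.ndarray:
        """Boolean mask for the half-open window [start_s, end_s)."""
        return (self.t >= start_s) & (self.t < end_s)
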