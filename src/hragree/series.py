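"""Core containers: timestamped heart-rate series and segment annotations.

An :class:`HRSeries` holds one device's (or the chest-strap reference's)
heart-rate samples for one session as parallel timestamp/value arrays.
A :class:`SegmentAnnotation` labels half-open time windows ``[start, end)``
of a session with the activity being performed and the climate chamber the
participant is in; the windows are non-overlapping and ordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: device label reserved for the gold-standard reference series
REFERENCE_LABEL = "reference"

SERIES_COLUMNS = ["subject_id", "session_id", "device", "timestamp_s", "hr_bpm"]
ANNOTATION_COLUMNS = ["session_id", "start_s", "end_s", "activity", "climate"]


@dataclass
class HRSeries:
    """One heart-rate time series: ``(timestamp s, HR bpm)`` samples.

    Timestamps are seconds from session start, strictly increasing;
    heart rate is strictly positive (bpm).
    """

    subject_id: str
    session_id: str
    device: str
    t: np.ndarray
    hr: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.hr.shape:
            raise ValueError("t and hr must be 1-d arrays of equal length")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError(f"timestamps must be strictly increasing ({self.session_id}/{self.device})")
        if np.any(self.hr <= 0):
            raise ValueError(f"heart rate must be > 0 bpm ({self.session_id}/{self.device})")

    @property
    def n(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Span in seconds from first to last sample (0 for <2 samples)."""
        return float(self.t[-1] - self.t[0]) if self.n > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "session_id": self.session_id,
                "device": self.device,
                "timestamp_s": self.t,
                "hr_bpm": self.hr,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HRSeries":
        """Build from a long-format frame holding exactly one series."""
        keys = df[["subject_id", "session_id", "device"]].drop_duplicates()
        if len(keys) != 1:
            raise ValueError("frame must contain exactly one (subject, session, device) series")
        sub, ses, dev = (str(v) for v in keys.iloc[0])
        df = df.sort_values("timestamp_s")
        return cls(sub, ses, dev, df["timestamp_s"].to_numpy(float), df["hr_bpm"].to_numpy(float))


@dataclass(frozen=True)
class Segment:
    """A labeled half-open window ``[start, end)`` in seconds."""

    start: float
    end: float
    activity: str
    climate: str

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"segment end must exceed start ({self.start}, {self.end})")


@dataclass
class SegmentAnnotation:
    """Ordered, non-overlapping activity x climate windows for one session."""

    session_id: str
    entries: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.start)
        for a, b in zip(self.entries, self.entries[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping segments at t={b.start} in {self.session_id}")

    @property
    def activities(self) -> set[str]:
        return {e.activity for e in self.entries}

    @property
    def climates(self) -> set[str]:
        return {e.climate for e in self.entries}

    @property
    def span(self) -> tuple[float, float]:
        return self.entries[0].start, self.entries[-1].end

    def segment_index(self, t: np.ndarray) -> np.ndarray:
        """Index of the entry covering each timestamp; -1 where uncovered."""
        t = np.asarray(t, dtype=float)
        starts = np.array([e.start for e in self.entries])
        ends = np.array([e.end for e in self.entries])
        idx = np.searchsorted(starts, t, side="right") - 1
        idx = np.where((idx >= 0) & (t < ends[np.clip(idx, 0, None)]), idx, -1)
        return idx

    def labels_at(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(activity, climate) label arrays for timestamps; raises if uncovered."""
        idx = self.segment_index(t)
        if np.any(idx < 0):
            bad = np.asarray(t)[idx < 0][:3]
            raise ValueError(f"timestamps not covered by annotation {self.session_id}: {bad}")
        act = np.array([e.activity for e in self.entries], dtype=object)
        clim = np.array([e.climate for e in self.entries], dtype=object)
        return act[idx], clim[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "session_id": self.session_id,
                    "start_s": e.start,
                    "end_s": e.end,
                    "activity": e.activity,
                    "climate": e.climate,
                }
                for e in self.entries
            ],
            columns=ANNOTATION_COLUMNS,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SegmentAnnotation":
        sess = df["session_id"].unique()
        if len(sess) != 1:
            raise ValueError("frame must contain exactly one session")
        entries = [
            Segment(float(r.start_s), float(r.end_s), str(r.activity), str(r.climate))
            for r in df.itertuples()
        ]
        return cls(str(sess[0]), entries)
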