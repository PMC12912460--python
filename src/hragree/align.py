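"""Timestamp-based synchronization of device and reference series.

Matching is reference-driven: each reference sample is greedily matched, in
time order, to the nearest unused device sample within a tolerance; reference
samples with no admissible device sample are excluded (and counted). No
smoothing or outlier removal is applied. Matched pairs can then be sliced by
activity and/or climate using the session's segment annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .series import HRSeries, SegmentAnnotation


@dataclass(frozen=True)
class MatchPolicy:
    """Matching tolerance (s) and tie rule.

    ``nearest-then-earlier`` picks the closest unused device sample, breaking
    exact distance ties toward the earlier sample; ``earlier`` picks the
    earliest unused device sample within tolerance.
    """

    tolerance_s: float = 0.5
    tie_rule: str = "nearest-then-earlier"

    def __post_init__(self) -> None:
        if self.tolerance_s <= 0:
            raise ValueError("matching tolerance must be positive")
        if self.tie_rule not in ("nearest-then-earlier", "earlier"):
            raise ValueError(f"unknown tie rule {self.tie_rule!r}")


@dataclass
class AlignedPairs:
    """Matched (reference, device) HR samples, plus excluded reference times."""

    subject_id: str
    session_id: str
    device: str
    t_ref: np.ndarray
    hr_ref: np.ndarray
    hr_dev: np.ndarray
    t_excluded: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.t_ref = np.asarray(self.t_ref, dtype=float)
        self.hr_ref = np.asarray(self.hr_ref, dtype=float)
        self.hr_dev = np.asarray(self.hr_dev, dtype=float)
        self.t_excluded = np.asarray(self.t_excluded, dtype=float)
        if not (self.t_ref.shape == self.hr_ref.shape == self.hr_dev.shape):
            raise ValueError("pair arrays must have equal length")
        if self.t_ref.size > 1 and np.any(np.diff(self.t_ref) <= 0):
            raise ValueError("pairs must be ordered by strictly increasing reference time")

    @property
    def n_pairs(self) -> int:
        return int(self.t_ref.size)

    @property
    def n_excluded(self) -> int:
        return int(self.t_excluded.size)

    @property
    def differences(self) -> np.ndarray:
        """Device minus reference, bpm."""
        return self.hr_dev - self.hr_ref

    @classmethod
    def from_values(
        cls,
        hr_ref: Iterable[float],
        hr_dev: Iterable[float],
        subject_id: str = "P01",
        session_id: str = "S01",
        device: str = "device",
    ) -> "AlignedPairs":
        """Convenience constructor pairing values on an implicit 1 Hz grid."""
        hr_ref = np.asarray(list(hr_ref), dtype=float)
        hr_dev = np.asarray(list(hr_dev), dtype=float)
        return cls(subject_id, session_id, device, np.arange(hr_ref.size, dtype=float), hr_ref, hr_dev)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "session_id": self.session_id,
                "device": self.device,
                "timestamp_s": self.t_ref,
                "hr_ref_bpm": self.hr_ref,
                "hr_dev_bpm": self.hr_dev,
            }
        )


def align_series(reference: HRSeries, device: HRSeries, policy: MatchPolicy | None = None) -> AlignedPairs:
    """Greedy one-to-one reference-to-device matching within tolerance.

    Raises if the series come from different sessions or the reference is
    empty. An empty device series yields zero pairs with every reference
    sample excluded.
    """
    policy = policy or MatchPolicy()
    if reference.session_id != device.session_id:
        raise ValueError(
            f"session mismatch: reference {reference.session_id!r} vs device {device.session_id!r}"
        )
    if reference.n == 0:
        raise ValueError("reference series is empty")

    tr, td = reference.t, device.t
    tol = policy.tolerance_s
    nearest = policy.tie_rule == "nearest-then-earlier"
    m = td.size

    matched_ref, matched_dev, excluded = [], [], []
    j = 0
    for i in range(tr.size):
        t = tr[i]
        # skip unused device samples that can no longer match any reference point
        while j < m and td[j] < t - tol:
            j += 1
        k = j
        if nearest:
            while k + 1 < m and abs(td[k + 1] - t) < abs(td[k] - t):
                k += 1
        if k < m and abs(td[k] - t) <= tol:
            matched_ref.append(i)
            matched_dev.append(k)
            j = k + 1
        else:
            excluded.append(t)

    idx = np.array(matched_ref, dtype=int)
    jdx = np.array(matched_dev, dtype=int)
    return AlignedPairs(
        reference.subject_id,
        reference.session_id,
        device.device,
        tr[idx],
        reference.hr[idx],
        device.hr[jdx],
        np.array(excluded, dtype=float),
    )


def _as_set(value: str | Iterable[str] | None) -> set[str] | None:
    if value is None:
        return None
    if isinstance(value, str):
        return {value}
    return set(value)


def slice_by_segment(
    aligned: AlignedPairs,
    annotation: SegmentAnnotation,
    activity: str | Iterable[str] | None = None,
    climate: str | Iterable[str] | None = None,
) -> AlignedPairs:
    """Retain pairs whose reference timestamp falls in a matching segment.

    Filters may restrict activity, climate, or both; an empty result is
    legitimate. Unknown filter labels raise. Excluded reference timestamps
    are filtered with the same rule, so the count identity
    ``n_pairs + n_excluded = n_reference`` holds per slice as well.
    """
    acts = _as_set(activity)
    clims = _as_set(climate)
    if acts is not None and not acts <= annotation.activities:
        raise ValueError(f"unknown activity labels {sorted(acts - annotation.activities)}")
    if clims is not None and not clims <= annotation.climates:
        raise ValueError(f"unknown climate labels {sorted(clims - annotation.climates)}")

    def keep_mask(t: np.ndarray) -> np.ndarray:
        if t.size == 0:
            return np.zeros(0, dtype=bool)
        act, clim = annotation.labels_at(t)
        mask = np.ones(t.size, dtype=bool)
        if acts is not None:
            mask &= np.isin(act, list(acts))
        if clims is not None:
            mask &= np.isin(clim, list(clims))
        return mask

    mask = keep_mask(aligned.t_ref)
    emask = keep_mask(aligned.t_excluded)
    return AlignedPairs(
        aligned.subject_id,
        aligned.session_id,
        aligned.device,
        aligned.t_ref[mask],
        aligned.hr_ref[mask],
        aligned.hr_dev[mask],
        aligned.t_excluded[emask],
    )
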