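"""Experimental protocol: 3 climate chambers x 6 fixed tasks.

The default protocol mirrors a wearable-validation session: in each of three
climate-controlled chambers (neutral 23 degC / 50% RH, hot 36 degC / 70% RH,
cold 10 degC / 40% RH) the participant performs six tasks in fixed order —
seated rest (6 min), a computerized cognitive stressor (MIST, 4 min), seated
recovery (2 min), steady treadmill walking (4 min), intermittent walking with
alternating 30 s walk/stand bouts (4 min), and standing rest (2 min) — 22
minutes per chamber. Chamber order is counterbalanced across subjects: half
run neutral-hot-cold, half neutral-cold-hot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .series import Segment, SegmentAnnotation

# canonical activity labels
REST = "rest"
MIST = "mist"
RECOVERY = "recovery"
WALKING = "walking"
WALKING_INTERMITTENT = "walking_intermittent"
STANDING = "standing"

#: the three activities compared in the per-activity analysis
ANALYSIS_ACTIVITIES = (MIST, WALKING, WALKING_INTERMITTENT)

#: walk/stand bout length inside the intermittent-walking task (s)
INTERMITTENT_BOUT_S = 30.0


@dataclass(frozen=True)
class Task:
    label: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("task duration must be positive")


@dataclass(frozen=True)
class Climate:
    label: str
    temperature_c: float
    humidity_pct: float


DEFAULT_TASKS = (
    Task(REST, 360.0),
    Task(MIST, 240.0),
    Task(RECOVERY, 120.0),
    Task(WALKING, 240.0),
    Task(WALKING_INTERMITTENT, 240.0),
    Task(STANDING, 120.0),
)

DEFAULT_CLIMATES = (
    Climate("neutral", 23.0, 50.0),
    Climate("hot", 36.0, 70.0),
    Climate("cold", 10.0, 40.0),
)


@dataclass
class ProtocolSpec:
    """Ordered climates and tasks; the task block repeats once per climate."""

    climates: tuple[Climate, ...] = DEFAULT_CLIMATES
    tasks: tuple[Task, ...] = DEFAULT_TASKS

    def __post_init__(self) -> None:
        if len(self.climates) != 3:
            raise ValueError("protocol requires exactly 3 climates")
        if len({c.label for c in self.climates}) != 3:
            raise ValueError("climate labels must be distinct")
        if not self.tasks:
            raise ValueError("protocol requires at least one task")

    @property
    def climate_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.climates)

    @property
    def climate_duration_s(self) -> float:
        """Seconds spent in each chamber (sum of the task durations)."""
        return float(sum(t.duration_s for t in self.tasks))

    @property
    def total_duration_s(self) -> float:
        return self.climate_duration_s * len(self.climates)

    def validate_order(self, climate_order: tuple[str, ...]) -> None:
        if sorted(climate_order) != sorted(self.climate_labels):
            raise ValueError(f"climate order {climate_order} is not a permutation of {self.climate_labels}")

    def annotation(self, session_id: str, climate_order: tuple[str, ...]) -> SegmentAnnotation:
        """Segment the session timeline for a given chamber order."""
        self.validate_order(climate_order)
        entries, t = [], 0.0
        for climate in climate_order:
            for task in self.tasks:
                entries.append(Segment(t, t + task.duration_s, task.label, climate))
                t += task.duration_s
        return SegmentAnnotation(session_id, entries)


def default_protocol() -> ProtocolSpec:
    return ProtocolSpec()


def counterbalanced_orders(n_subjects: int, protocol: ProtocolSpec | None = None) -> list[tuple[str, ...]]:
    """Chamber order per subject: the first climate always leads, the other
    two alternate (even-indexed subjects get (c0, c1, c2), odd get (c0, c2, c1))."""
    protocol = protocol or default_protocol()
    c0, c1, c2 = protocol.climate_labels
    return [(c0, c1, c2) if i % 2 == 0 else (c0, c2, c1) for i in range(n_subjects)]
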