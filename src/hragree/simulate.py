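"""Synthetic study generator.

Produces paired reference/device heart-rate series with the statistical
structure the downstream agreement analysis assumes:

* a latent "true" HR per subject that relaxes toward an activity- and
  climate-dependent target with first-order dynamics plus AR(1)
  physiological noise, sampled at 1 Hz (the reference chest strap);
* device observations obtained by resampling the truth on the device's
  reporting grid (regular, or irregular with integer gaps), adding a
  per-subject calibration bias, i.i.d. measurement noise, and motion-artifact
  runs whose probability depends on the activity being performed;
* a study design emulating 45 subjects wearing 2 wrist devices each (plus a
  finger ring for a subset), every device covered by 10 sessions, with
  counterbalanced chamber order.

Seeding is counter-based: per-subject and per-device streams are spawned
from the master seed with fixed spawn keys, so adding subjects or devices
never perturbs the data of earlier ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .protocol import (
    ANALYSIS_ACTIVITIES,
    INTERMITTENT_BOUT_S,
    MIST,
    RECOVERY,
    REST,
    STANDING,
    WALKING,
    WALKING_INTERMITTENT,
    ProtocolSpec,
    counterbalanced_orders,
    default_protocol,
)
from .series import REFERENCE_LABEL, HRSeries, SegmentAnnotation

log = logging.getLogger(__name__)

HR_MIN, HR_MAX = 1.0, 250.0  # physiological clamp for generated series

DEFAULT_ACTIVITY_INCREMENTS: dict[str, float] = {
    REST: 0.0,
    MIST: 12.0,
    RECOVERY: 4.0,
    WALKING: 45.0,
    WALKING_INTERMITTENT: 45.0,  # walk bouts; stand bouts use the standing increment
    STANDING: 8.0,
}

DEFAULT_CLIMATE_INCREMENTS: dict[str, float] = {"neutral": 0.0, "hot": 8.0, "cold": -3.0}


@dataclass
class SubjectParams:
    """Latent-HR model for one subject.

    ``baseline_hr`` is resting HR (bpm); activity/climate increments shift the
    segment target; the series relaxes toward the target with time constant
    ``tau_s`` and carries AR(1) noise (coefficient ``ar_coef``, innovation sd
    ``noise_sd`` bpm).
    """

    baseline_hr: float = 65.0
    activity_increments: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_INCREMENTS)
    )
    climate_increments: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLIMATE_INCREMENTS)
    )
    tau_s: float = 40.0
    noise_sd: float = 2.0
    ar_coef: float = 0.9

    def __post_init__(self) -> None:
        if not 35.0 <= self.baseline_hr <= 120.0:
            raise ValueError(f"baseline HR {self.baseline_hr} outside [35, 120] bpm")
        if self.tau_s <= 0:
            raise ValueError("response time constant tau must be positive")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def draw_subject_params(rng: np.random.Generator, baseline_mean: float = 65.0, baseline_sd: float = 7.0) -> SubjectParams:
    """Sample a subject: baseline ~ Normal(65, 7^2) bpm clipped to [40, 110]."""
    baseline = float(np.clip(rng.normal(baseline_mean, baseline_sd), 40.0, 110.0))
    return SubjectParams(baseline_hr=baseline)


@dataclass(frozen=True)
class RegularSampling:
    """Fixed reporting interval in seconds."""

    interval_s: float = 1.0

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ValueError("sampling interval must be positive")

    def times(self, t0: float, t1: float, rng: np.random.Generator) -> np.ndarray:
        n = int(np.floor((t1 - t0) / self.interval_s)) + 1
        return t0 + self.interval_s * np.arange(n)


@dataclass(frozen=True)
class IrregularSampling:
    """Integer reporting gaps drawn uniformly from {min_s .. max_s} seconds."""

    min_s: int = 1
    max_s: int = 7

    def __post_init__(self) -> None:
        if self.min_s < 1 or self.max_s < self.min_s:
            raise ValueError("irregular sampling requires 1 <= min_s <= max_s")

    def times(self, t0: float, t1: float, rng: np.random.Generator) -> np.ndarray:
        span = t1 - t0
        n_max = int(span / self.min_s) + 2
        gaps = rng.integers(self.min_s, self.max_s + 1, size=n_max)
        t = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
        return t[t <= t1 + 1e-9]


Sampling = RegularSampling | IrregularSampling


@dataclass
class DeviceErrorModel:
    """Observation model for one wearable.

    Device HR = truth(resampled) + b_i + e, with a per-subject calibration
    bias b_i ~ Normal(mean_bias, between_subject_sd^2) drawn once per subject,
    i.i.d. noise e ~ Normal(0, noise_sd^2), and artifact runs (hold-last-value
    and/or additive excursions) started per sample with an activity-dependent
    probability and geometric run length.
    """

    label: str = "device"
    site: str = "wrist"  # wrist | finger
    mean_bias: float = 0.0
    between_subject_sd: float = 0.0
    noise_sd: float = 0.0
    sampling: Sampling = field(default_factory=lambda: IrregularSampling(1, 7))
    artifact_prob: Mapping[str, float] = field(default_factory=dict)
    artifact_sd: float = 25.0
    artifact_run_mean: float = 5.0
    artifact_mode: str = "mixed"  # hold | excursion | mixed

    def __post_init__(self) -> None:
        if self.between_subject_sd < 0 or self.noise_sd < 0 or self.artifact_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for act, p in self.artifact_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"artifact probability for {act!r} outside [0, 1]")
        if self.artifact_run_mean < 1:
            raise ValueError("artifact run-length mean must be >= 1 sample")
        if self.artifact_mode not in ("hold", "excursion", "mixed"):
            raise ValueError(f"unknown artifact mode {self.artifact_mode!r}")
        if self.site not in ("wrist", "finger"):
            raise ValueError(f"unknown wearing site {self.site!r}")


SeedLike = int | np.random.SeedSequence


def generate_true_hr(
    subject: SubjectParams,
    protocol: ProtocolSpec,
    climate_order: tuple[str, ...],
    seed: SeedLike,
    subject_id: str = "P01",
    session_id: str = "S01",
) -> HRSeries:
    """Latent 1 Hz HR over the whole session (reference series).

    The target in each segment is baseline + activity increment + climate
    increment; within the intermittent-walking task the target alternates
    between the walking and standing levels every 30 s. HR follows
    ``h[t] = h[t-1] + step * (target[t] - h[t-1]) + ar_noise[t]`` with
    ``step = min(1, 1/tau)``, and is clamped to (0, 250] bpm.
    """
    protocol.validate_order(climate_order)
    rng = np.random.default_rng(seed)

    ann = protocol.annotation(session_id, climate_order)
    n = int(round(protocol.total_duration_s))
    t = np.arange(n, dtype=float)

    target = np.empty(n)
    for seg in ann.entries:
        i0, i1 = np.searchsorted(t, [seg.start, seg.end])
        base = subject.baseline_hr + subject.climate_increments.get(seg.climate, 0.0)
        if seg.activity == WALKING_INTERMITTENT:
            # alternate walk/stand bouts, walking first
            bout = ((t[i0:i1] - seg.start) // INTERMITTENT_BOUT_S).astype(int)
            inc = np.where(
                bout % 2 == 0,
                subject.activity_increments.get(WALKING, 0.0),
                subject.activity_increments.get(STANDING, 0.0),
            )
            target[i0:i1] = base + inc
        else:
            target[i0:i1] = base + subject.activity_increments.get(seg.activity, 0.0)

    step = min(1.0, 1.0 / subject.tau_s)
    innov = rng.normal(0.0, subject.noise_sd, size=n)
    ar = lfilter([1.0], [1.0, -subject.ar_coef], innov)

    # deterministic relaxation det[t] = a1*det[t-1] + step*target[t], with the
    # stationary AR(1) fluctuation added on top: folding the innovation into
    # the relaxation recursion would amplify its variance by ~(tau^2), so the
    # noise scale is kept independent of tau
    a1 = 1.0 - step
    det = np.empty(n)
    det[0] = subject.baseline_hr
    if n > 1:
        det[1:] = lfilter([step], [1.0, -a1], target[1:], zi=[a1 * det[0]])[0]
    h = det + ar

    if np.any(h < HR_MIN) or np.any(h > HR_MAX):
        log.warning("true HR clamped to (%.0f, %.0f] bpm for %s", HR_MIN, HR_MAX, session_id)
        h = np.clip(h, HR_MIN, HR_MAX)

    return HRSeries(subject_id, session_id, REFERENCE_LABEL, t, h)


def _artifact_runs(
    values: np.ndarray,
    prob: np.ndarray,
    model: DeviceErrorModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Overlay artifact runs on device values (hold-last-value / excursions)."""
    out = values.copy()
    n = out.size
    u = rng.random(n)
    i = 0
    while i < n:
        if prob[i] > 0 and u[i] < prob[i]:
            run = int(rng.geometric(1.0 / model.artifact_run_mean))
            stop = min(i + run, n)
            mode = model.artifact_mode
            if mode == "mixed":
                mode = "hold" if rng.random() < 0.5 else "excursion"
            if mode == "hold":
                out[i:stop] = out[i - 1] if i > 0 else out[i]
            else:
                out[i:stop] = out[i:stop] + rng.normal(0.0, model.artifact_sd)
            i = stop
        else:
            i += 1
    return out


def apply_device_model(
    truth: HRSeries,
    model: DeviceErrorModel,
    seed: SeedLike,
    annotation: SegmentAnnotation | None = None,
) -> HRSeries:
    """Observe the latent series through a device's error model.

    ``annotation`` is required whenever any artifact probability is nonzero
    (artifact rates depend on the activity label at each sample).
    """
    if truth.n == 0:
        raise ValueError("cannot apply a device model to an empty truth series")
    rng = np.random.default_rng(seed)

    bias = rng.normal(model.mean_bias, model.between_subject_sd)
    times = model.sampling.times(truth.t[0], truth.t[-1], rng)
    values = np.interp(times, truth.t, truth.hr) + bias
    values = values + rng.normal(0.0, model.noise_sd, size=times.size)

    if any(p > 0 for p in model.artifact_prob.values()):
        if annotation is None:
            raise ValueError("annotation required when artifact probabilities are nonzero")
        act, _ = annotation.labels_at(times)
        prob = np.array([model.artifact_prob.get(a, 0.0) for a in act])
        values = _artifact_runs(values, prob, model, rng)

    values = np.clip(values, HR_MIN, None)
    return HRSeries(truth.subject_id, truth.session_id, model.label, times, values)


# ---------------------------------------------------------------------------
# study-level generation

WATCH_LABELS = tuple(f"watch_{i:02d}" for i in range(1, 10))
RING_LABEL = "ring_01"


def default_device_models() -> dict[str, DeviceErrorModel]:
    """Ten invented wearables spanning good-to-poor accuracy.

    Numeric values are generator defaults chosen to span the accuracy range a
    heterogeneous panel of consumer PPG wearables exhibits (low-bias/low-noise
    trackers through heavily artifact-prone ones); they are study conditions,
    not estimates of any particular product.
    """
    irr = IrregularSampling(1, 7)
    one_hz = RegularSampling(1.0)

    def m(label, site, bias, sb, se, sampling, p_walk, p_int, p_mist=0.0):
        prob = {WALKING: p_walk, WALKING_INTERMITTENT: p_int}
        if p_mist:
            prob[MIST] = p_mist
        return DeviceErrorModel(
            label=label, site=site, mean_bias=bias, between_subject_sd=sb,
            noise_sd=se, sampling=sampling, artifact_prob=prob,
        )

    models = [
        m("watch_01", "wrist", 0.5, 1.5, 2.5, irr, 0.02, 0.05),
        m("watch_02", "wrist", -12.0, 9.0, 8.0, irr, 0.10, 0.30),
        m("watch_03", "wrist", 4.0, 5.0, 5.0, irr, 0.05, 0.10),
        m("watch_04", "wrist", -1.0, 4.0, 4.0, irr, 0.03, 0.08),
        m("watch_05", "wrist", 1.0, 5.0, 5.0, irr, 0.04, 0.12),
        m("watch_06", "wrist", -0.5, 3.0, 3.5, irr, 0.03, 0.06),
        m("watch_07", "wrist", -4.0, 6.0, 6.0, one_hz, 0.08, 0.20),
        m("watch_08", "wrist", -4.0, 6.0, 6.5, one_hz, 0.06, 0.18),
        m("watch_09", "wrist", -3.0, 7.0, 5.5, irr, 0.06, 0.15),
        m("ring_01", "finger", -7.0, 7.0, 6.0, one_hz, 0.05, 0.12, 0.02),
    ]
    return {mm.label: mm for mm in models}


def default_assignments(
    n_subjects: int = 45,
    watch_labels: Sequence[str] = WATCH_LABELS,
    ring_label: str | None = RING_LABEL,
    n_ring: int = 10,
) -> dict[int, tuple[str, ...]]:
    """Round-robin: 2 watches per subject (each watch covered equally often);
    the first ``n_ring`` subjects additionally wear the ring."""
    k = len(watch_labels)
    out: dict[int, tuple[str, ...]] = {}
    c = 0
    for i in range(n_subjects):
        devs = [watch_labels[c % k], watch_labels[(c + 1) % k]]
        c += 2
        if ring_label is not None and i < n_ring:
            devs.append(ring_label)
        out[i] = tuple(devs)
    return out


def assignments_for_models(
    n_subjects: int, models: Mapping[str, DeviceErrorModel]
) -> dict[int, tuple[str, ...]]:
    """Balanced assignment for an arbitrary device panel: up to 2 wrist
    devices per subject round-robin (equal coverage), finger devices worn by
    every subject."""
    wrist = [l for l, m in models.items() if m.site == "wrist"]
    finger = [l for l, m in models.items() if m.site == "finger"]
    out: dict[int, tuple[str, ...]] = {}
    c = 0
    for i in range(n_subjects):
        devs: list[str] = []
        if wrist:
            for _ in range(min(2, len(wrist))):
                devs.append(wrist[c % len(wrist)])
                c += 1
        devs.extend(finger)
        out[i] = tuple(devs)
    return out


@dataclass
class StudyData:
    """All generated series, per-session annotations, and the design table."""

    series: list[HRSeries]
    annotations: list[SegmentAnnotation]
    design: pd.DataFrame

    @property
    def references(self) -> list[HRSeries]:
        return [s for s in self.series if s.device == REFERENCE_LABEL]

    @property
    def device_series(self) -> list[HRSeries]:
        return [s for s in self.series if s.device != REFERENCE_LABEL]


def generate_study(
    n_subjects: int = 45,
    assignments: Mapping[int, tuple[str, ...]] | None = None,
    protocol: ProtocolSpec | None = None,
    models: Mapping[str, DeviceErrorModel] | None = None,
    master_seed: SeedLike = 0,
) -> StudyData:
    """Generate the full synthetic study.

    Each subject contributes one session: a 1 Hz reference series plus one
    series per assigned device. At most two wrist-site devices per subject
    (finger-site devices are exempt). Per-subject streams are spawned from
    the master seed with subject-indexed keys.
    """
    protocol = protocol or default_protocol()
    if assignments is None:
        assignments = (
            default_assignments(n_subjects)
            if models is None
            else assignments_for_models(n_subjects, models)
        )
    models = dict(models) if models is not None else default_device_models()
    model_order = list(models)

    for i in range(n_subjects):
        devs = assignments.get(i, ())
        unknown = [d for d in devs if d not in models]
        if unknown:
            raise ValueError(f"subject {i}: unknown device labels {unknown}")
        n_wrist = sum(1 for d in devs if models[d].site == "wrist")
        if n_wrist > 2:
            raise ValueError(f"subject {i}: {n_wrist} wrist devices assigned (max 2; ring exempt)")

    orders = counterbalanced_orders(n_subjects, protocol)
    entropy = master_seed.entropy if isinstance(master_seed, np.random.SeedSequence) else master_seed

    series: list[HRSeries] = []
    annotations: list[SegmentAnnotation] = []
    rows = []
    for i in range(n_subjects):
        subject_id, session_id = f"P{i + 1:02d}", f"S{i + 1:02d}"
        params_seed = np.random.SeedSequence(entropy, spawn_key=(i, 0))
        truth_seed = np.random.SeedSequence(entropy, spawn_key=(i, 1))
        subject = draw_subject_params(np.random.default_rng(params_seed))
        truth = generate_true_hr(subject, protocol, orders[i], truth_seed, subject_id, session_id)
        ann = protocol.annotation(session_id, orders[i])
        series.append(truth)
        annotations.append(ann)
        wrist_sides = ["left", "right"] if i % 2 == 0 else ["right", "left"]
        w = 0
        for dev in assignments.get(i, ()):
            model = models[dev]
            dev_seed = np.random.SeedSequence(entropy, spawn_key=(i, 2 + model_order.index(dev)))
            series.append(apply_device_model(truth, model, dev_seed, ann))
            if model.site == "wrist":
                side = wrist_sides[w]
                w += 1
            else:
                side = "finger"
            rows.append(
                {
                    "subject_id": subject_id,
                    "session_id": session_id,
                    "device": dev,
                    "site": side,
                    "climate_order": "-".join(orders[i]),
                }
            )

    design = pd.DataFrame(rows, columns=["subject_id", "session_id", "device", "site", "climate_order"])
    return StudyData(series, annotations, design)
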