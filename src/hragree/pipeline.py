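"""End-to-end validation pipeline: simulate -> align -> slice -> metrics -> compare.

Produces the three reporting tables — overall, by climate, by activity —
one row per device x stratum with MAE/MAPE median (IQR), repeated-measures
CCC, and mixed-effects Bland-Altman bias and limits of agreement; plus the
comparison-test table and a run report with per-stage record counts.

The unit of all between-device and between-condition tests is the
per-session metric (one MAE/MAPE value per device session and stratum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    BlandAltman,
    mae,
    mape,
    fit_agreement_lmm,
    mixed_effects_bland_altman,
    rm_ccc,
    stack_method_long,
    summarize_device,
)
from .align import AlignedPairs, MatchPolicy, align_series, slice_by_segment
from .protocol import ANALYSIS_ACTIVITIES, ProtocolSpec, default_protocol
from .series import REFERENCE_LABEL, HRSeries, SegmentAnnotation
from .simulate import DeviceErrorModel, StudyData, generate_study
from .stats import ComparisonPlan, results_to_frame, run_comparison, shapiro_wilk_gate

log = logging.getLogger(__name__)

OVERALL = "overall"

SUMMARY_COLUMNS = [
    "device", "stratum", "mae_median", "mae_q1", "mae_q3",
    "mape_median", "mape_q1", "mape_q3", "ccc", "bias",
    "loa_lower", "loa_upper", "n_sessions",
]


class ConfigError(Exception):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(Exception):
    """Invalid or inconsistent input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Configuration for one validation run.

    Either simulate (``n_subjects``/``models``/``assignments``; ``seed``
    mandatory) or analyze existing data (``series``/``annotations``).
    ``climate_strata`` selects whether per-climate metrics cover all tasks in
    the chamber ("all_tasks", default) or only the three analyzed activities
    ("activities_only").
    """

    seed: int | None = 0
    n_subjects: int = 45
    protocol: ProtocolSpec = field(default_factory=default_protocol)
    models: Mapping[str, DeviceErrorModel] | None = None
    assignments: Mapping[int, tuple[str, ...]] | None = None
    series: list[HRSeries] | None = None
    annotations: list[SegmentAnnotation] | None = None
    policy: MatchPolicy = field(default_factory=MatchPolicy)
    climate_strata: str = "all_tasks"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.climate_strata not in ("all_tasks", "activities_only"):
            raise ConfigError(f"unknown climate_strata {self.climate_strata!r}")
        if self.series is None and self.seed is None:
            raise ConfigError("seed is mandatory when simulating")
        if (self.series is None) != (self.annotations is None):
            raise ConfigError("series and annotations must be provided together")


@dataclass
class RunReport:
    """Per-stage record counts and provenance for one run."""

    samples_read: int = 0
    reference_samples: int = 0
    pairs_matched: int = 0
    reference_excluded: int = 0
    n_sessions: int = 0
    n_devices: int = 0
    friedman_blocks_dropped: int = 0
    shapiro_gates: list[dict] = field(default_factory=list)
    version: str = __version__
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "samples_read": self.samples_read,
            "reference_samples": self.reference_samples,
            "pairs_matched": self.pairs_matched,
            "reference_excluded": self.reference_excluded,
            "n_sessions": self.n_sessions,
            "n_devices": self.n_devices,
            "friedman_blocks_dropped": self.friedman_blocks_dropped,
            "shapiro_gates": self.shapiro_gates,
            "version": self.version,
            "config_echo": self.config_echo,
        }


@dataclass
class ValidationResult:
    overall: pd.DataFrame
    by_climate: pd.DataFrame
    by_activity: pd.DataFrame
    tests: pd.DataFrame
    session_metrics: pd.DataFrame
    report: RunReport


def _study_from_config(config: RunConfig) -> StudyData:
    if config.series is not None:
        refs = [s for s in config.series if s.device == REFERENCE_LABEL]
        devs = [s for s in config.series if s.device != REFERENCE_LABEL]
        if not refs:
            raise DataError("no reference series in input")
        design = pd.DataFrame(
            [{"subject_id": s.subject_id, "session_id": s.session_id, "device": s.device} for s in devs]
        )
        return StudyData(config.series, config.annotations or [], design)
    return generate_study(
        n_subjects=config.n_subjects,
        assignments=config.assignments,
        protocol=config.protocol,
        models=config.models,
        master_seed=config.seed,
    )


def align_study(study: StudyData, policy: MatchPolicy) -> list[AlignedPairs]:
    """Align every device series of every session against its reference."""
    refs = {s.session_id: s for s in study.references}
    aligned = []
    for dev in study.device_series:
        ref = refs.get(dev.session_id)
        if ref is None:
            raise DataError(f"align: no reference series for session {dev.session_id}")
        aligned.append(align_series(ref, dev, policy))
    return aligned


def session_metric_table(
    aligned: list[AlignedPairs],
    annotations: Mapping[str, SegmentAnnotation],
    climate_strata: str = "all_tasks",
) -> pd.DataFrame:
    """Per-session MAE/MAPE per stratum (overall, each climate, each activity)."""
    rows = []
    for ap in aligned:
        ann = annotations[ap.session_id]
        strata: list[tuple[str, AlignedPairs]] = [(OVERALL, ap)]
        for climate in sorted(ann.climates):
            sl = slice_by_segment(ap, ann, climate=climate)
            if climate_strata == "activities_only":
                sl = slice_by_segment(ap, ann, activity=ANALYSIS_ACTIVITIES, climate=climate)
            strata.append((climate, sl))
        for activity in ANALYSIS_ACTIVITIES:
            strata.append((activity, slice_by_segment(ap, ann, activity=activity)))
        for name, sl in strata:
            if sl.n_pairs == 0:
                log.warning("no pairs for %s/%s stratum %s", ap.session_id, ap.device, name)
                continue
            rows.append(
                {
                    "device": ap.device,
                    "session_id": ap.session_id,
                    "subject_id": ap.subject_id,
                    "stratum": name,
                    "mae": mae(sl),
                    "mape": mape(sl),
                    "n_pairs": sl.n_pairs,
                }
            )
    return pd.DataFrame(
        rows, columns=["device", "session_id", "subject_id", "stratum", "mae", "mape", "n_pairs"]
    )


def _stratum_slices(
    aligned: list[AlignedPairs],
    annotations: Mapping[str, SegmentAnnotation],
    stratum: str,
    kind: str,
    climate_strata: str,
) -> list[AlignedPairs]:
    out = []
    for ap in aligned:
        ann = annotations[ap.session_id]
        if kind == "overall":
            sl = ap
        elif kind == "climate":
            acts = ANALYSIS_ACTIVITIES if climate_strata == "activities_only" else None
            sl = slice_by_segment(ap, ann, activity=acts, climate=stratum)
        else:
            sl = slice_by_segment(ap, ann, activity=stratum)
        if sl.n_pairs:
            out.append(sl)
    return out


def summarize_stratum(
    device: str,
    stratum: str,
    slices: list[AlignedPairs],
    session_metrics: pd.DataFrame,
) -> dict:
    """One table row: session medians plus pooled model-based agreement."""
    long = stack_method_long(slices)
    vc = fit_agreement_lmm(long)
    diffs = np.concatenate([p.differences for p in slices])
    subjects = np.concatenate([np.repeat(p.subject_id, p.n_pairs) for p in slices])
    ba = mixed_effects_bland_altman(diffs, subjects)
    summ = summarize_device(device, stratum, session_metrics, vc, ba)
    return {
        "device": summ.device,
        "stratum": summ.stratum,
        "mae_median": summ.mae_median,
        "mae_q1": summ.mae_q1,
        "mae_q3": summ.mae_q3,
        "mape_median": summ.mape_median,
        "mape_q1": summ.mape_q1,
        "mape_q3": summ.mape_q3,
        "ccc": summ.ccc,
        "bias": summ.bias,
        "loa_lower": summ.loa_lower,
        "loa_upper": summ.loa_upper,
        "n_sessions": summ.n_sessions,
    }


def run_full_validation(config: RunConfig) -> ValidationResult:
    """Execute the whole pipeline; deterministic given the seed."""
    study = _study_from_config(config)
    annotations = {a.session_id: a for a in study.annotations}

    try:
        aligned = align_study(study, config.policy)
    except ValueError as e:
        raise DataError(f"align: {e}") from e

    report = RunReport(
        samples_read=int(sum(s.n for s in study.series)),
        reference_samples=int(sum(s.n for s in study.references)),
        pairs_matched=int(sum(a.n_pairs for a in aligned)),
        reference_excluded=int(sum(a.n_excluded for a in aligned)),
        n_sessions=len({a.session_id for a in aligned}),
        n_devices=len({a.device for a in aligned}),
        config_echo={
            "seed": config.seed,
            "n_subjects": config.n_subjects,
            "tolerance_s": config.policy.tolerance_s,
            "tie_rule": config.policy.tie_rule,
            "climate_strata": config.climate_strata,
            "alpha": config.alpha,
        },
    )

    metrics = session_metric_table(aligned, annotations, config.climate_strata)
    if metrics.empty:
        raise DataError("metrics: no per-session metrics could be computed")

    climates = sorted({c for a in study.annotations for c in a.climates})
    by_device = {d: [a for a in aligned if a.device == d] for d in sorted({a.device for a in aligned})}

    def table(strata: list[str], kind: str) -> pd.DataFrame:
        rows = []
        for device, dev_aligned in by_device.items():
            for stratum in strata:
                sm = metrics[(metrics["device"] == device) & (metrics["stratum"] == stratum)]
                slices = _stratum_slices(dev_aligned, annotations, stratum, kind, config.climate_strata)
                if sm.empty or not slices:
                    log.warning("summary: no data for %s x %s", device, stratum)
                    continue
                try:
                    rows.append(summarize_stratum(device, stratum, slices, sm))
                except ValueError as e:
                    raise DataError(f"summary {device} x {stratum}: {e}") from e
        return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)

    overall = table([OVERALL], "overall")
    by_climate = table(climates, "climate")
    by_activity = table(list(ANALYSIS_ACTIVITIES), "activity")

    # normality gate (logged; the comparison ladder is nonparametric throughout)
    for (device, stratum), sub in metrics.groupby(["device", "stratum"]):
        for metric in ("mae", "mape"):
            values = sub[metric].to_numpy()
            if values.size >= 3 and np.ptp(values) > 0:
                w, p, normal = shapiro_wilk_gate(values, config.alpha)
                report.shapiro_gates.append(
                    {"device": device, "stratum": stratum, "metric": metric,
                     "W": round(w, 4), "p": p, "normal": normal}
                )

    results = []
    for metric in ("mae", "mape"):
        results += run_comparison(ComparisonPlan("device", metric, config.alpha), metrics)
        climate_rows = metrics[metrics["stratum"].isin(climates + [OVERALL])]
        results += run_comparison(ComparisonPlan("climate", metric, config.alpha), climate_rows)
        activity_rows = metrics[metrics["stratum"].isin(list(ANALYSIS_ACTIVITIES) + [OVERALL])]
        results += run_comparison(ComparisonPlan("activity", metric, config.alpha), activity_rows)
    tests = results_to_frame(results)

    return ValidationResult(overall, by_climate, by_activity, tests, metrics, report)


def _display_variant(df: pd.DataFrame) -> pd.DataFrame:
    """1-decimal bpm/% display rounding; CCC shown at 2 decimals."""
    out = df.copy()
    one_dp = [c for c in out.columns if c.startswith(("mae", "mape", "bias", "loa"))]
    for c in one_dp:
        out[c] = out[c].map(lambda v: f"{v:.1f}")
    if "ccc" in out.columns:
        out["ccc"] = out["ccc"].map(lambda v: f"{v:.2f}")
    return out


def write_tables(result: ValidationResult, out_dir: str | Path) -> pd.DataFrame:
    """Write machine- and display-precision CSVs plus the run report.

    Returns the manifest (file name, row count) as a DataFrame; also written
    as ``manifest.csv``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise DataError(f"cannot create output directory {out}: {e}") from e

    import json

    files: list[tuple[str, pd.DataFrame]] = [
        ("overall.csv", result.overall),
        ("by_climate.csv", result.by_climate),
        ("by_activity.csv", result.by_activity),
        ("tests.csv", result.tests),
        ("session_metrics.csv", result.session_metrics),
    ]
    manifest_rows = []
    for name, df in files:
        df.to_csv(out / name, index=False, float_format="%.10g")
        manifest_rows.append({"file": name, "rows": len(df)})
        if name in ("overall.csv", "by_climate.csv", "by_activity.csv"):
            disp = name.replace(".csv", "_display.csv")
            _display_variant(df).to_csv(out / disp, index=False)
            manifest_rows.append({"file": disp, "rows": len(df)})

    with open(out / "report.json", "w") as fh:
        json.dump(result.report.to_dict(), fh, indent=2, default=float)
    manifest_rows.append({"file": "report.json", "rows": 1})

    manifest = pd.DataFrame(manifest_rows, columns=["file", "rows"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
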