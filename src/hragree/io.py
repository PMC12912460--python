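"""CSV and YAML input/output.

Long-format series CSV: ``subject_id,session_id,device,timestamp_s,hr_bpm``;
annotation CSV: ``session_id,start_s,end_s,activity,climate``. These schemas
are the contract for real-device exports as well as for the synthetic
generator.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .align import MatchPolicy
from .series import ANNOTATION_COLUMNS, SERIES_COLUMNS, HRSeries, SegmentAnnotation
from .simulate import DeviceErrorModel, IrregularSampling, RegularSampling


def write_series_csv(series: Iterable[HRSeries], path: str | Path) -> None:
    df = pd.concat([s.to_frame() for s in series], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.6f")


def read_series_csv(path: str | Path) -> list[HRSeries]:
    df = pd.read_csv(path)
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"series CSV missing columns {sorted(missing)}")
    out = []
    for _, sub in df.groupby(["subject_id", "session_id", "device"], sort=True):
        out.append(HRSeries.from_frame(sub))
    return out


def write_annotation_csv(annotations: Iterable[SegmentAnnotation], path: str | Path) -> None:
    df = pd.concat([a.to_frame() for a in annotations], ignore_index=True)
    df.to_csv(path, index=False)


def read_annotation_csv(path: str | Path) -> list[SegmentAnnotation]:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns {sorted(missing)}")
    return [SegmentAnnotation.from_frame(sub) for _, sub in df.groupby("session_id", sort=True)]


def _sampling_from_dict(d: Mapping) -> RegularSampling | IrregularSampling:
    kind = d.get("kind", "irregular")
    if kind == "regular":
        return RegularSampling(float(d.get("interval_s", 1.0)))
    if kind == "irregular":
        return IrregularSampling(int(d.get("min_s", 1)), int(d.get("max_s", 7)))
    raise ValueError(f"unknown sampling kind {kind!r}")


def device_model_from_dict(label: str, d: Mapping) -> DeviceErrorModel:
    """Build a device error model from a YAML mapping."""
    return DeviceErrorModel(
        label=label,
        site=d.get("site", "wrist"),
        mean_bias=float(d.get("mean_bias", 0.0)),
        between_subject_sd=float(d.get("between_subject_sd", 0.0)),
        noise_sd=float(d.get("noise_sd", 0.0)),
        sampling=_sampling_from_dict(d.get("sampling", {})),
        artifact_prob={k: float(v) for k, v in d.get("artifact_prob", {}).items()},
        artifact_sd=float(d.get("artifact_sd", 25.0)),
        artifact_run_mean=float(d.get("artifact_run_mean", 5.0)),
        artifact_mode=d.get("artifact_mode", "mixed"),
    )


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def match_policy_from_config(cfg: Mapping) -> MatchPolicy:
    return MatchPolicy(
        tolerance_s=float(cfg.get("tolerance_s", 0.5)),
        tie_rule=cfg.get("tie_rule", "nearest-then-earlier"),
    )
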