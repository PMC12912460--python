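"""Agreement statistics between device and reference heart rate.

Four statistics are computed per device and stratum:

* MAE (bpm) and MAPE (%) per session, summarized across sessions as
  median (IQR) with the linear-interpolation ("type 7") quantile rule;
* a repeated-measures concordance correlation coefficient (CCC) from the
  variance components of a linear mixed model — stacked reference+device
  observations, a fixed method effect, and a random intercept per subject,
  estimated by REML:

      CCC = sigma2_between / (sigma2_between + sigma2_within + delta^2 / 2)

  where ``delta`` is the device-minus-reference fixed effect;
* a mixed-effects Bland-Altman analysis of the device-minus-reference
  differences: ``difference ~ 1`` with a random intercept per subject,
  bias = the fixed intercept, limits of agreement = bias +/- 1.96 x
  sqrt(sigma2_between + sigma2_within).

Degenerate layouts reduce to their classical counterparts: one observation
per subject makes the mixed-effects Bland-Altman identical to the classic
mean +/- 1.96 SD analysis, and a single subject makes the CCC model fall
back to per-pair grouping, reproducing Lin's concordance on the raw pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .align import AlignedPairs
from .series import REFERENCE_LABEL

log = logging.getLogger(__name__)

LOA_MULTIPLIER = 1.96  # normal 95% quantile, conventional Bland-Altman
_ZERO_VAR = 1e-10


def mae(pairs: AlignedPairs) -> float:
    """Mean absolute error in bpm. Raises on empty input (MAE 0 is meaningful)."""
    if pairs.n_pairs == 0:
        raise ValueError("MAE undefined for zero pairs")
    return float(np.mean(np.abs(pairs.hr_dev - pairs.hr_ref)))


def mape(pairs: AlignedPairs) -> float:
    """Mean absolute percentage error, % of the reference value."""
    if pairs.n_pairs == 0:
        raise ValueError("MAPE undefined for zero pairs")
    if np.any(pairs.hr_ref <= 0):
        raise ValueError("MAPE requires strictly positive reference HR")
    return float(np.mean(np.abs(pairs.hr_dev - pairs.hr_ref) / pairs.hr_ref) * 100.0)


@dataclass
class VarianceComponents:
    """REML variance components of the two-method agreement model."""

    var_between: float  # between-subject variance, bpm^2
    var_within: float  # residual (within-subject) variance, bpm^2
    method_diff: float  # device minus reference fixed effect, bpm
    grand_mean: float  # overall mean HR, bpm

    def __post_init__(self) -> None:
        if self.var_between < 0 or self.var_within < 0:
            raise ValueError("variance components must be >= 0")


def stack_method_long(pairs_list: Iterable[AlignedPairs]) -> pd.DataFrame:
    """Stack aligned pairs into the long two-method layout for the LMM.

    Columns: ``subject``, ``pair`` (a unique id per matched pair), ``method``
    ("reference" or "device"), ``hr``.
    """
    frames = []
    for p in pairs_list:
        pair_id = [f"{p.session_id}:{p.device}:{k}" for k in range(p.n_pairs)]
        frames.append(
            pd.DataFrame(
                {
                    "subject": p.subject_id,
                    "pair": pair_id * 2,
                    "method": [REFERENCE_LABEL] * p.n_pairs + ["device"] * p.n_pairs,
                    "hr": np.concatenate([p.hr_ref, p.hr_dev]),
                }
            )
        )
    if not frames:
        raise ValueError("no aligned pairs to stack")
    return pd.concat(frames, ignore_index=True)


def _moment_components(groups: np.ndarray, is_dev: np.ndarray, hr: np.ndarray) -> VarianceComponents:
    """Balanced ANOVA estimator, used when the residual variance vanishes."""
    delta = float(hr[is_dev].mean() - hr[~is_dev].mean())
    centered = hr - np.where(is_dev, delta / 2.0, -delta / 2.0)
    gmeans = pd.Series(centered).groupby(pd.Series(groups)).mean().to_numpy()
    var_a = float(np.var(gmeans, ddof=1)) if gmeans.size > 1 else 0.0
    return VarianceComponents(var_a, _ZERO_VAR, delta, float(hr.mean()))


def _fit_random_intercept(endog: np.ndarray, exog: np.ndarray, groups: np.ndarray):
    """REML MixedLM fit robust to false boundary solutions.

    The default optimizer occasionally collapses the random-intercept
    variance to zero and drags the fixed effects with it; when that happens
    the fit is retried with Powell and the solution with the higher REML
    log-likelihood is kept.
    """
    model = sm.MixedLM(endog, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
        boundary = float(np.asarray(res.cov_re)[0, 0]) < _ZERO_VAR
        if boundary or not res.converged:
            alt = sm.MixedLM(endog, exog, groups=groups).fit(reml=True, method="powell")
            llf = res.llf if np.isfinite(res.llf) else -np.inf
            alt_llf = alt.llf if np.isfinite(alt.llf) else -np.inf
            if alt_llf > llf:
                log.warning("mixed-model refit (Powell) improved a boundary solution")
                res = alt
    return res


def fit_agreement_lmm(data: pd.DataFrame) -> VarianceComponents:
    """REML fit of ``hr ~ method`` with a random intercept per subject.

    ``data`` is the long two-method layout from :func:`stack_method_long`.
    Requires both methods observed for every subject. With a single subject
    the grouping unit falls back to the matched pair (column ``pair``), the
    reduction under which the model-based CCC coincides with Lin's
    concordance on the raw pairs; a warning is logged.
    """
    required = {"subject", "method", "hr"}
    if not required <= set(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    methods = set(data["method"].unique())
    if len(methods) != 2 or REFERENCE_LABEL not in methods:
        raise ValueError("exactly two methods required, one of them 'reference'")

    per_subject = data.groupby("subject")["method"].nunique()
    if (per_subject < 2).any():
        raise ValueError("both methods must be observed for every subject")

    if per_subject.size < 2:
        if "pair" not in data.columns:
            raise ValueError("single-subject data requires a 'pair' column")
        log.warning("single subject: grouping by matched pair (Lin's CCC reduction)")
        groups = data["pair"].to_numpy()
    else:
        groups = data["subject"].to_numpy()

    hr = data["hr"].to_numpy(float)
    is_dev = (data["method"] != REFERENCE_LABEL).to_numpy()

    # residual variance after removing group x method cell means; if it
    # vanishes the REML fit is degenerate and the ANOVA moments are exact
    cell = pd.DataFrame({"g": groups, "m": is_dev, "y": hr})
    resid = hr - cell.groupby(["g", "m"])["y"].transform("mean").to_numpy()
    if float(np.var(resid)) < _ZERO_VAR:
        log.warning("zero within-cell variance: returning method-of-moments components")
        return _moment_components(groups, is_dev, hr)

    exog = np.column_stack([np.ones(hr.size), is_dev.astype(float)])
    res = _fit_random_intercept(hr, exog, groups)
    var_a = float(np.asarray(res.cov_re)[0, 0])
    var_e = float(res.scale)
    if var_a < _ZERO_VAR:
        log.warning("between-subject variance estimated at the zero boundary")
        var_a = 0.0
    return VarianceComponents(var_a, var_e, float(np.asarray(res.fe_params)[1]), float(hr.mean()))


def rm_ccc(vc: VarianceComponents) -> float:
    """Repeated-measures CCC from variance components (two-method form)."""
    total = vc.var_between + vc.var_within
    if total <= _ZERO_VAR:
        raise ValueError("agreement undefined: all variance components are zero")
    return float(vc.var_between / (vc.var_between + vc.var_within + vc.method_diff**2 / 2.0))


def _lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance on raw pairs; internal oracle for degeneracy tests."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2 * sxy / (x.var() + y.var() + (x.mean() - y.mean()) ** 2))


@dataclass
class BlandAltman:
    """Mixed-effects Bland-Altman bias and 95% limits of agreement (bpm)."""

    bias: float
    loa_lower: float
    loa_upper: float
    var_between: float
    var_within: float
    n: int

    @property
    def half_width(self) -> float:
        return (self.loa_upper - self.loa_lower) / 2.0


def mixed_effects_bland_altman(
    differences: Sequence[float] | np.ndarray,
    subjects: Sequence[str] | np.ndarray,
) -> BlandAltman:
    """Bias and limits of agreement accounting for repeated measures.

    Fits ``difference ~ 1`` with a random intercept per subject (REML);
    bias is the fixed intercept and the limits are bias +/- 1.96 x
    sqrt(var_between + var_within). Degenerate layouts (a single subject, or
    one observation per subject) reduce to the classic Bland-Altman analysis
    with the between-subject component set to zero (logged).
    """
    d = np.asarray(differences, dtype=float)
    g = np.asarray(subjects)
    if d.size != g.size:
        raise ValueError("differences and subjects must have equal length")
    if d.size < 2:
        raise ValueError("at least 2 differences required")

    if float(np.ptp(d)) == 0.0:
        b = float(d[0])
        return BlandAltman(b, b, b, 0.0, 0.0, d.size)

    counts = pd.Series(d).groupby(pd.Series(g)).size()
    if counts.size == 1 or (counts == 1).all():
        if counts.size == 1:
            log.warning("single subject: between-subject variance set to 0 (classic Bland-Altman)")
        bias = float(d.mean())
        var_w = float(np.var(d, ddof=1))
        sd = np.sqrt(var_w)
        return BlandAltman(
            bias, bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd, 0.0, var_w, d.size
        )

    res = _fit_random_intercept(d, np.ones((d.size, 1)), np.asarray(g, dtype=object))
    bias = float(np.asarray(res.fe_params)[0])
    var_b = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
    var_w = float(res.scale)
    sd = float(np.sqrt(var_b + var_w))
    return BlandAltman(
        bias, bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd, var_b, var_w, d.size
    )


@dataclass
class AgreementSummary:
    """One row of the reporting tables: a device x stratum summary."""

    device: str
    stratum: str
    mae_median: float
    mae_q1: float
    mae_q3: float
    mape_median: float
    mape_q1: float
    mape_q3: float
    ccc: float
    bias: float
    loa_lower: float
    loa_upper: float
    n_sessions: int

    def __post_init__(self) -> None:
        if not (self.loa_lower <= self.bias <= self.loa_upper):
            raise ValueError("limits of agreement must bracket the bias")
        if not -1.0 <= self.ccc <= 1.0:
            raise ValueError("CCC must lie in [-1, 1]")
        if self.mae_q1 > self.mae_q3 or self.mape_q1 > self.mape_q3:
            raise ValueError("IQR bounds out of order")


def median_iqr(values: Sequence[float] | np.ndarray) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median undefined on empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def summarize_device(
    device: str,
    stratum: str,
    session_metrics: pd.DataFrame,
    vc: VarianceComponents,
    ba: BlandAltman,
) -> AgreementSummary:
    """Combine per-session MAE/MAPE with pooled model-based agreement.

    ``session_metrics`` needs one row per session with columns ``mae`` and
    ``mape``; ``vc`` and ``ba`` come from the pooled per-subject data of the
    same stratum.
    """
    if len(session_metrics) < 1:
        raise ValueError("at least one session required")
    mae_med, mae_q1, mae_q3 = median_iqr(session_metrics["mae"])
    mape_med, mape_q1, mape_q3 = median_iqr(session_metrics["mape"])
    return AgreementSummary(
        device=device,
        stratum=stratum,
        mae_median=mae_med,
        mae_q1=mae_q1,
        mae_q3=mae_q3,
        mape_median=mape_med,
        mape_q1=mape_q1,
        mape_q3=mape_q3,
        ccc=rm_ccc(vc),
        bias=ba.bias,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
        n_sessions=len(session_metrics),
    )
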