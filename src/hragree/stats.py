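"""Nonparametric comparison ladder for per-session error metrics.

The inferential workflow mirrors standard device-validation practice:
a Shapiro-Wilk normality gate (alpha = .05), then robust nonparametric
omnibus tests — Kruskal-Wallis across independent device groups, Friedman
across repeated within-device conditions — followed, only on a significant
omnibus, by pairwise post-hocs (Wilcoxon rank-sum between devices, Wilcoxon
signed-rank between conditions) at a Bonferroni-corrected alpha, each with a
rank-biserial effect size r in [-1, 1].

Exact p-values are used for the pairwise tests whenever the sample is small
(n <= 25) and tie-free; otherwise the normal approximation with continuity
and tie correction applies. Zero differences in the signed-rank test are
discarded (classic Wilcoxon zero handling; Pratt ranking available by flag).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

EXACT_N_MAX = 25  # exact <-> normal-approximation switchover for Wilcoxon tests


@dataclass
class TestResult:
    """One hypothesis test with its multiplicity context.

    ``effect_r`` is the rank-biserial correlation (pairwise tests only; None
    for omnibus tests). ``reject`` compares the unrounded p-value with the
    corrected alpha.
    """

    family: str
    test: str
    unit: str  # device under test for condition factors, "all" for device factor
    group_a: str
    group_b: str
    statistic: float
    p: float
    alpha_nominal: float
    alpha_corrected: float
    m: int
    reject: bool
    effect_r: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.effect_r is not None and abs(self.effect_r) > 1.0 + 1e-12:
            raise ValueError("rank-biserial r outside [-1, 1]")


def bonferroni(alpha: float, m: int) -> float:
    """Family-wise corrected threshold alpha / m (compare p-values unrounded;
    round to 4 decimals only for display)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return alpha / m


def shapiro_wilk_gate(values: Sequence[float] | np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk normality test; returns (W, p, normal = p >= alpha).

    Requires 3 <= n <= 5000 and non-degenerate variance.
    """
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if float(np.ptp(v)) == 0.0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    w, p = sps.shapiro(v)
    return float(w), float(p), bool(p >= alpha)


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    m: int = 1,
    family: str = "device",
    unit: str = "all",
) -> TestResult:
    """Kruskal-Wallis H (tie-corrected), p from chi-square with k-1 df."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("Kruskal-Wallis groups must be nonempty")
    h, p = sps.kruskal(*[np.asarray(g, float) for g in groups])
    a_corr = bonferroni(alpha, m)
    return TestResult(
        family, "kruskal-wallis", unit, "", "", float(h), float(p), alpha, a_corr, m, bool(p < a_corr)
    )


def friedman(
    blocks: np.ndarray | pd.DataFrame,
    alpha: float = 0.05,
    m: int = 1,
    family: str = "condition",
    unit: str = "all",
) -> TestResult:
    """Friedman chi-square over complete blocks (rows) x conditions (columns).

    Ties within a block receive average ranks with the usual tie correction.
    Missing cells raise: the caller must drop incomplete blocks (and log the
    count). Two-condition designs are not supported (use the signed-rank
    test, to which Friedman is then equivalent).
    """
    x = np.asarray(blocks, dtype=float)
    if x.ndim != 2:
        raise ValueError("blocks must be a 2-d (blocks x conditions) array")
    if np.isnan(x).any():
        raise ValueError("incomplete blocks: drop rows with missing cells before testing")
    n, k = x.shape
    if k == 2:
        raise ValueError("Friedman with 2 conditions reduces to the signed-rank test; use that")
    if k < 2 or n < 2:
        raise ValueError("Friedman requires >= 2 blocks and >= 2 conditions")
    if np.all(np.ptp(x, axis=1) == 0):
        stat, p = 0.0, 1.0  # every block constant: no within-block ranking information
    else:
        stat, p = sps.friedmanchisquare(*[x[:, j] for j in range(k)])
    a_corr = bonferroni(alpha, m)
    return TestResult(
        family, "friedman", unit, "", "", float(stat), float(p), alpha, a_corr, m, bool(p < a_corr)
    )


def _rank_biserial_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U1, r): U1 counts (x > y) pairs with 1/2 per tie; r = 2 U1/(n1 n2) - 1."""
    u1 = float(
        np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :])
    )
    r = 2.0 * u1 / (x.size * y.size) - 1.0
    return u1, r


def wilcoxon_rank_sum(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    alpha: float = 0.05,
    m: int = 1,
    family: str = "device",
    unit: str = "all",
    group_a: str = "x",
    group_b: str = "y",
) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) with rank-biserial r.

    Exact p when min(n1, n2) <= 25 and the pooled sample is tie-free;
    otherwise the normal approximation with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= EXACT_N_MAX and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    u1, r = _rank_biserial_rank_sum(x, y)
    a_corr = bonferroni(alpha, m)
    return TestResult(
        family, "wilcoxon-rank-sum", unit, group_a, group_b,
        u1, float(res.pvalue), alpha, a_corr, m, bool(res.pvalue < a_corr), r,
    )


def wilcoxon_signed_rank(
    differences: Sequence[float] | np.ndarray,
    alpha: float = 0.05,
    m: int = 1,
    family: str = "condition",
    unit: str = "all",
    group_a: str = "a",
    group_b: str = "b",
    zero_method: str = "wilcox",
) -> TestResult:
    """One-sample Wilcoxon signed-rank on paired differences.

    Zeros are discarded by default (classic Wilcoxon; ``zero_method="pratt"``
    keeps them in the ranking). Effect size r = (W+ - W-)/(W+ + W-). Exact p
    for n <= 25 without tied absolute values, else normal approximation with
    continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("no differences supplied")
    n_zero = int(np.sum(d == 0))
    if zero_method == "wilcox":
        if n_zero:
            log.info("signed-rank: discarding %d zero difference(s)", n_zero)
        d_used = d[d != 0]
    elif zero_method == "pratt":
        d_used = d
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    if d_used.size == 0 or np.all(d == 0):
        raise ValueError("all differences are zero: signed-rank test undefined")

    ties = np.unique(np.abs(d_used)).size < d_used.size
    method = "exact" if (d_used.size <= EXACT_N_MAX and not ties and n_zero == 0) else "approx"
    res = sps.wilcoxon(
        d, zero_method=zero_method, correction=True, alternative="two-sided", method=method
    )

    # rank-biserial from signed ranks of the nonzero differences
    nz = d[d != 0]
    ranks = sps.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    w_neg = float(ranks[nz < 0].sum())
    r = (w_pos - w_neg) / (w_pos + w_neg)

    a_corr = bonferroni(alpha, m)
    return TestResult(
        family, "wilcoxon-signed-rank", unit, group_a, group_b,
        w_pos, float(res.pvalue), alpha, a_corr, m, bool(res.pvalue < a_corr), r,
    )


@dataclass
class ComparisonPlan:
    """How one factor is tested on one per-session metric.

    ``factor`` "device" uses independent-group tests (Kruskal-Wallis omnibus,
    rank-sum post-hocs, one omnibus per metric, uncorrected); "climate" and
    "activity" use repeated-measures tests per device (Friedman omnibus at
    alpha / n_devices, signed-rank post-hocs at alpha / n_condition_pairs).
    """

    factor: str  # device | climate | activity
    metric: str  # mae | mape
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.factor not in ("device", "climate", "activity"):
            raise ValueError(f"unknown factor {self.factor!r}")
        if self.metric not in ("mae", "mape"):
            raise ValueError(f"unknown metric {self.metric!r}")


def run_comparison(plan: ComparisonPlan, metrics: pd.DataFrame) -> list[TestResult]:
    """Execute omnibus + gated post-hoc tests for one plan.

    ``metrics`` needs columns ``device``, ``session_id``, ``stratum`` and the
    plan's metric. For the device factor the rows with ``stratum == "overall"``
    are used; for condition factors the strata are the condition labels and
    incomplete blocks (sessions missing a condition) are dropped with a log
    message. Post-hoc tests run only when the omnibus rejects.
    """
    needed = {"device", "session_id", "stratum", plan.metric}
    if not needed <= set(metrics.columns):
        raise ValueError(f"metrics table must have columns {sorted(needed)}")
    results: list[TestResult] = []
    fam = f"{plan.factor}:{plan.metric}"

    if plan.factor == "device":
        overall = metrics[metrics["stratum"] == "overall"]
        if overall.empty:
            raise ValueError("no 'overall' stratum rows for the device comparison")
        devices = sorted(overall["device"].unique())
        groups = [overall.loc[overall["device"] == d, plan.metric].to_numpy() for d in devices]
        omni = kruskal_wallis(groups, plan.alpha, m=1, family=fam, unit="all")
        results.append(omni)
        if omni.reject:
            pairs = list(itertools.combinations(devices, 2))
            m = len(pairs)
            for a, b in pairs:
                results.append(
                    wilcoxon_rank_sum(
                        overall.loc[overall["device"] == a, plan.metric],
                        overall.loc[overall["device"] == b, plan.metric],
                        plan.alpha, m=m, family=fam, unit="all", group_a=a, group_b=b,
                    )
                )
        return results

    # condition factor: one repeated-measures ladder per device
    cond_rows = metrics[metrics["stratum"] != "overall"]
    conditions = sorted(cond_rows["stratum"].unique())
    devices = sorted(cond_rows["device"].unique())
    n_omnibus = len(devices)
    for dev in devices:
        sub = cond_rows[cond_rows["device"] == dev]
        wide = sub.pivot_table(index="session_id", columns="stratum", values=plan.metric)
        wide = wide.reindex(columns=conditions)
        complete = wide.dropna()
        dropped = len(wide) - len(complete)
        if dropped:
            log.info("%s %s: dropped %d incomplete block(s)", fam, dev, dropped)
        if len(complete) < 2:
            log.warning("%s %s: fewer than 2 complete blocks, omnibus skipped", fam, dev)
            continue
        omni = friedman(complete.to_numpy(), plan.alpha, m=n_omnibus, family=fam, unit=dev)
        results.append(omni)
        if omni.reject:
            pairs = list(itertools.combinations(conditions, 2))
            m = len(pairs)
            for a, b in pairs:
                diffs = (complete[b] - complete[a]).to_numpy()
                results.append(
                    wilcoxon_signed_rank(
                        diffs, plan.alpha, m=m, family=fam, unit=dev, group_a=a, group_b=b
                    )
                )
    return results


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Flatten test results for reporting (corrected alpha shown at 4 dp)."""
    rows = []
    for t in results:
        rows.append(
            {
                "family": t.family,
                "test": t.test,
                "unit": t.unit,
                "group_a": t.group_a,
                "group_b": t.group_b,
                "statistic": t.statistic,
                "p": t.p,
                "alpha_corrected": round(t.alpha_corrected, 4),
                "m": t.m,
                "reject": t.reject,
                "effect_r": t.effect_r,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family", "test", "unit", "group_a", "group_b",
            "statistic", "p", "alpha_corrected", "m", "reject", "effect_r",
        ],
    )
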