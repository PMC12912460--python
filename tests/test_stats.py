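"""Nonparametric ladder: hand values, exhaustive oracles, and gating."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hragree.stats import (
    ComparisonPlan,
    bonferroni,
    friedman,
    kruskal_wallis,
    run_comparison,
    shapiro_wilk_gate,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


class TestShapiroGate:
    def test_keeps_normal_data_most_of_the_time(self):
        rng = np.random.default_rng(10)
        kept = sum(shapiro_wilk_gate(rng.normal(size=50))[2] for _ in range(1000))
        assert kept >= 900  # type-I error ~ alpha = .05

    def test_flags_heavy_skew(self):
        rng = np.random.default_rng(11)
        flagged = sum(not shapiro_wilk_gate(np.exp(rng.normal(size=50)))[2] for _ in range(1000))
        assert flagged >= 950

    def test_degenerate_and_tiny_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk_gate([3.0, 3.0, 3.0])
        with pytest.raises(ValueError, match="3 <= n"):
            shapiro_wilk_gate([1.0, 2.0])


class TestKruskalWallis:
    def test_hand_computed_h_without_ties(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.p == pytest.approx(float(sps.chi2.sf(7.2, 2)))

    def test_identical_groups_give_null_boundary(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_equivalent_to_rank_sum_normal_approximation(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=30), rng.normal(0.5, 1, 35)
        res = kruskal_wallis([x, y])
        mw = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                              use_continuity=False)
        assert res.p == pytest.approx(float(mw.pvalue), abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            kruskal_wallis([[1.0], []])


class TestFriedman:
    def test_hand_computed_chi_square(self):
        # both blocks rank the conditions identically: chi2 = 0.5*56 - 24 = 4
        res = friedman(np.array([[10.0, 20.0, 30.0], [5.0, 15.0, 25.0]]))
        assert res.statistic == pytest.approx(4.0)
        assert res.p == pytest.approx(float(sps.chi2.sf(4.0, 2)))

    def test_constant_blocks_carry_no_evidence(self):
        res = friedman(np.full((5, 3), 7.0))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, 2.0, 3.0], [1.0, np.nan, 3.0]])
        with pytest.raises(ValueError, match="incomplete"):
            friedman(x)

    def test_two_conditions_rejected(self):
        with pytest.raises(ValueError, match="signed-rank"):
            friedman(np.array([[1.0, 2.0], [2.0, 1.0]]))


def _exact_rank_sum_p(x, y):
    """Enumerate all C(n1+n2, n1) labelings; two-sided p of observed U1."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)

    def u1(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        return np.sum(xs[:, None] > ys[None, :]) + 0.5 * np.sum(xs[:, None] == ys[None, :])

    us = np.array([u1(ix) for ix in itertools.combinations(range(n), n1)])
    obs = u1(range(n1))
    mu = len(x) * len(y) / 2.0
    return float(np.mean(np.abs(us - mu) >= abs(obs - mu) - 1e-12))


def _exact_signed_rank_p(d):
    """Enumerate all 2^n sign patterns of |d|; two-sided p of observed W+."""
    a = np.abs(d)
    ranks = sps.rankdata(a)
    w_obs = ranks[np.asarray(d) > 0].sum()
    n = len(d)
    ws = np.array([
        ranks[np.array(signs, dtype=bool)].sum()
        for signs in itertools.product([0, 1], repeat=n)
    ])
    mu = ranks.sum() / 2.0
    return float(np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-12))


class TestWilcoxonRankSum:
    def test_complete_separation_gives_unit_effect(self):
        res = wilcoxon_rank_sum([10, 11, 12], [1, 2, 3])
        assert res.effect_r == pytest.approx(1.0)

    def test_hand_enumerated_pairs(self):
        res = wilcoxon_rank_sum([1, 2, 4], [3, 5])
        assert res.statistic == pytest.approx(1.0)  # U1: only 4 > 3
        assert res.effect_r == pytest.approx(-2 / 3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_p_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(1.0, 9.0))[:4]
        y = np.setdiff1d(np.arange(1.0, 9.0), x)
        res = wilcoxon_rank_sum(x, y)
        assert res.p == pytest.approx(_exact_rank_sum_p(x, y), abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        x=st.lists(st.floats(-50, 50), min_size=2, max_size=15),
        y=st.lists(st.floats(-50, 50), min_size=2, max_size=15),
    )
    def test_rank_biserial_antisymmetry(self, x, y):
        assert wilcoxon_rank_sum(x, y).effect_r == pytest.approx(
            -wilcoxon_rank_sum(y, x).effect_r, abs=1e-12
        )


class TestWilcoxonSignedRank:
    def test_all_positive_differences_give_unit_effect(self):
        assert wilcoxon_signed_rank([1.0, 2.0, 3.5]).effect_r == pytest.approx(1.0)

    def test_hand_ranked_balance(self):
        res = wilcoxon_signed_rank([1.0, 2.0, -3.0])
        assert res.statistic == pytest.approx(3.0)  # W+ = ranks of +1, +2
        assert res.effect_r == pytest.approx(0.0)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_sign_pattern_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = (np.arange(1.0, 9.0)) * rng.choice([-1, 1], 8)
        res = wilcoxon_signed_rank(d)
        assert res.p == pytest.approx(_exact_signed_rank_p(d), abs=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize(
        "m,rounded", [(45, 0.0011), (10, 0.005), (3, 0.0167)]
    )
    def test_printed_thresholds(self, m, rounded):
        assert round(bonferroni(0.05, m), 4) == rounded

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni(1.5, 3)

    def test_rejections_shrink_with_family_size(self):
        rng = np.random.default_rng(13)
        ps = rng.uniform(0, 0.2, 50)
        small = {i for i, p in enumerate(ps) if p < bonferroni(0.05, 5)}
        large = {i for i, p in enumerate(ps) if p < bonferroni(0.05, 25)}
        assert large <= small


def _metric_table(values_by_device, stratum="overall"):
    rows = []
    for dev, vals in values_by_device.items():
        for s, v in enumerate(vals):
            rows.append({"device": dev, "session_id": f"S{s}", "stratum": stratum,
                         "mae": v, "mape": v})
    return pd.DataFrame(rows)


class TestRunComparison:
    def test_ten_devices_yield_45_posthoc_pairs(self):
        rng = np.random.default_rng(14)
        table = _metric_table({f"d{i}": rng.normal(3 + 2 * i, 0.3, 10) for i in range(10)})
        results = run_comparison(ComparisonPlan("device", "mae"), table)
        omni = [r for r in results if r.test == "kruskal-wallis"]
        post = [r for r in results if r.test == "wilcoxon-rank-sum"]
        assert len(omni) == 1 and omni[0].reject
        assert len(post) == 45 and all(r.m == 45 for r in post)
        assert all(r.alpha_corrected == pytest.approx(0.05 / 45) for r in post)

    def test_null_omnibus_gates_out_posthocs(self):
        # identical per-session values across devices: H = 0 exactly
        vals = list(np.linspace(2, 6, 10))
        table = _metric_table({f"d{i}": vals for i in range(4)})
        results = run_comparison(ComparisonPlan("device", "mae"), table)
        assert len(results) == 1 and not results[0].reject

    def test_activity_factor_uses_repeated_measures_ladder(self):
        rng = np.random.default_rng(15)
        rows = []
        for dev in ("a", "b"):
            for s in range(10):
                base = rng.normal(3, 0.2)
                for act, shift in (("mist", 0.0), ("walking", 0.5), ("walking_intermittent", 6.0)):
                    rows.append({"device": dev, "session_id": f"S{s}", "stratum": act,
                                 "mae": base + shift + rng.normal(0, 0.1), "mape": 1.0})
        results = run_comparison(ComparisonPlan("activity", "mae"), pd.DataFrame(rows))
        omni = [r for r in results if r.test == "friedman"]
        post = [r for r in results if r.test == "wilcoxon-signed-rank"]
        assert len(omni) == 2 and all(r.m == 2 for r in omni)  # alpha / n_devices
        assert all(r.reject for r in omni)
        assert len(post) == 2 * 3 and all(r.m == 3 for r in post)
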