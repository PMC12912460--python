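"""Error metrics, variance-components CCC, and mixed-effects Bland-Altman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hragree.agreement import (
    AgreementSummary,
    VarianceComponents,
    _lin_ccc,
    fit_agreement_lmm,
    mae,
    mape,
    median_iqr,
    mixed_effects_bland_altman,
    rm_ccc,
    stack_method_long,
    summarize_device,
)
from hragree.align import AlignedPairs


def P(ref, dev, **kw):
    return AlignedPairs.from_values(ref, dev, **kw)


class TestErrorMetrics:
    @pytest.mark.parametrize(
        "ref,dev,expected",
        [
            ([60, 80], [60, 80], 0.0),
            ([60, 80, 100], [63, 76, 105], 4.0),
            ([70], [80], 10.0),
        ],
    )
    def test_mae_hand_values(self, ref, dev, expected):
        assert mae(P(ref, dev)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "ref,dev,expected",
        [
            ([60, 80], [60, 80], 0.0),
            ([60, 80, 100], [63, 84, 105], 5.0),
            ([50], [60], 20.0),
        ],
    )
    def test_mape_hand_values(self, ref, dev, expected):
        assert mape(P(ref, dev)) == pytest.approx(expected)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            mae(P([], []))
        with pytest.raises(ValueError):
            mape(P([], []))

    def test_mape_requires_positive_reference(self):
        p = AlignedPairs("P01", "S01", "d", [0.0], [0.0], [50.0])
        p.hr_ref = np.array([-1.0])
        with pytest.raises(ValueError, match="positive"):
            mape(p)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ref=st.lists(st.floats(40, 180), min_size=1, max_size=30),
        dev=st.lists(st.floats(40, 180), min_size=30, max_size=30),
        scale=st.floats(0.1, 10),
    )
    def test_mape_scale_invariant_and_mae_dominates_bias(self, ref, dev, scale):
        dev = dev[: len(ref)]
        p = P(ref, dev)
        scaled = P(np.array(ref) * scale, np.array(dev) * scale)
        assert mape(scaled) == pytest.approx(mape(p), rel=1e-9)
        assert abs(np.mean(p.differences)) <= mae(p) + 1e-12


class TestMedianIQR:
    def test_linear_interpolation_rule(self):
        assert median_iqr([3, 4, 5]) == (4.0, 3.5, 4.5)

    def test_single_value_degenerates(self):
        assert median_iqr([7.0]) == (7.0, 7.0, 7.0)


def _simulate_two_method(rng, n_subj, n_pts, sd_subj, sd_eps, delta, mu=80.0):
    rows = []
    for i in range(n_subj):
        a = rng.normal(0.0, sd_subj)
        for method, off in (("reference", 0.0), ("device", delta)):
            y = mu + a + off + rng.normal(0.0, sd_eps, n_pts)
            rows.append(pd.DataFrame({"subject": f"P{i}", "pair": np.arange(n_pts),
                                      "method": method, "hr": y}))
    return pd.concat(rows, ignore_index=True)


class TestAgreementLMM:
    def test_constant_offset_recovers_fixed_effect_exactly(self):
        rng = np.random.default_rng(1)
        pairs = []
        for i in range(3):
            r = rng.uniform(60, 120, 50)
            pairs.append(AlignedPairs.from_values(r, r + 10.0, subject_id=f"P{i}", session_id=f"S{i}"))
        vc = fit_agreement_lmm(stack_method_long(pairs))
        assert vc.method_diff == pytest.approx(10.0, abs=1e-6)

    def test_noise_free_two_subject_degeneracy_matches_anova_oracle(self):
        """Two constant subjects at 60/80 with device == reference: the REML /
        balanced-ANOVA between-subject variance is (MSB - MSW) / n = 200."""
        pairs = [
            AlignedPairs.from_values([60.0] * 4, [60.0] * 4, subject_id="A"),
            AlignedPairs.from_values([80.0] * 4, [80.0] * 4, subject_id="B"),
        ]
        vc = fit_agreement_lmm(stack_method_long(pairs))
        assert vc.method_diff == pytest.approx(0.0, abs=1e-9)
        assert vc.var_within <= 1e-9
        assert vc.var_between == pytest.approx(200.0, rel=1e-6)

    def test_parameter_recovery_from_generating_model(self):
        """sigma2_a=100, sigma2_e=25, delta=0 at 200 subjects x 50 points:
        REML estimates land within 15% of the truth."""
        data = _simulate_two_method(np.random.default_rng(42), 200, 50, 10.0, 5.0, 0.0)
        vc = fit_agreement_lmm(data)
        assert vc.var_between == pytest.approx(100.0, rel=0.15)
        assert vc.var_within == pytest.approx(25.0, rel=0.15)
        assert vc.method_diff == pytest.approx(0.0, abs=0.5)

    def test_requires_both_methods_per_subject(self):
        df = pd.DataFrame({"subject": ["A", "A", "B"], "pair": [0, 0, 0],
                           "method": ["reference", "device", "reference"], "hr": [60, 61, 70]})
        with pytest.raises(ValueError, match="both methods"):
            fit_agreement_lmm(df)


class TestRmCCC:
    @pytest.mark.parametrize(
        "vb,vw,delta,expected",
        [
            (100.0, 0.0, 0.0, 1.0),
            (100.0, 25.0, 0.0, 0.8),
            (100.0, 0.0, 10.0, 2 / 3),
        ],
    )
    def test_closed_form_values(self, vb, vw, delta, expected):
        assert rm_ccc(VarianceComponents(vb, vw, delta, 80.0)) == pytest.approx(expected, abs=1e-9)

    def test_all_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            rm_ccc(VarianceComponents(0.0, 0.0, 1.0, 80.0))

    def test_monotone_decreasing_in_delta_and_residual(self):
        deltas = np.linspace(0, 20, 15)
        cccs = [rm_ccc(VarianceComponents(100.0, 25.0, d, 80.0)) for d in deltas]
        assert np.all(np.diff(cccs) < 0)
        resids = np.linspace(1, 200, 15)
        cccs = [rm_ccc(VarianceComponents(100.0, v, 3.0, 80.0)) for v in resids]
        assert np.all(np.diff(cccs) < 0)

    def test_single_subject_reduces_to_lin_ccc_on_noise_free_pairs(self):
        rng = np.random.default_rng(8)
        r = rng.uniform(55, 150, 200)
        pairs = [AlignedPairs.from_values(r, r, subject_id="only")]
        vc = fit_agreement_lmm(stack_method_long(pairs))
        assert rm_ccc(vc) == pytest.approx(_lin_ccc(r, r), abs=1e-6)
        assert _lin_ccc(r, r) == 1.0


class TestBlandAltman:
    def test_constant_differences_collapse_the_limits(self):
        ba = mixed_effects_bland_altman([5.0] * 6, ["A", "A", "B", "B", "C", "C"])
        assert (ba.bias, ba.loa_lower, ba.loa_upper) == (5.0, 5.0, 5.0)

    def test_recovers_generating_bias_and_limits(self):
        """Subject sd 3, within sd 4, mean -5: bias ~ -5 and LoA half-width
        ~ 1.96 * sqrt(9 + 16) = 9.8, each within +/- 0.5 bpm."""
        rng = np.random.default_rng(31)
        n_subj, n_pts = 200, 40
        subj = np.repeat([f"P{i}" for i in range(n_subj)], n_pts)
        d = (np.repeat(rng.normal(-5.0, 3.0, n_subj), n_pts)
             + rng.normal(0.0, 4.0, n_subj * n_pts))
        ba = mixed_effects_bland_altman(d, subj)
        assert ba.bias == pytest.approx(-5.0, abs=0.5)
        assert ba.half_width == pytest.approx(9.8, abs=0.5)

    def test_one_observation_per_subject_equals_classic_bland_altman(self):
        rng = np.random.default_rng(4)
        d = rng.normal(-2.0, 3.0, 40)
        ba = mixed_effects_bland_altman(d, [f"P{i}" for i in range(40)])
        sd = np.std(d, ddof=1)
        assert ba.bias == pytest.approx(d.mean(), abs=1e-9)
        assert ba.loa_upper == pytest.approx(d.mean() + 1.96 * sd, abs=1e-9)
        assert ba.loa_lower == pytest.approx(d.mean() - 1.96 * sd, abs=1e-9)

    def test_single_subject_falls_back_to_classic(self):
        rng = np.random.default_rng(5)
        d = rng.normal(1.0, 2.0, 30)
        ba = mixed_effects_bland_altman(d, ["only"] * 30)
        assert ba.var_between == 0.0
        assert ba.bias == pytest.approx(d.mean(), abs=1e-9)

    def test_fewer_than_two_differences_rejected(self):
        with pytest.raises(ValueError):
            mixed_effects_bland_altman([1.0], ["A"])

    def test_limits_symmetric_about_bias(self):
        rng = np.random.default_rng(6)
        d = np.concatenate([rng.normal(m, 2.0, 20) for m in (-3, 0, 4)])
        subj = np.repeat(list("ABC"), 20)
        ba = mixed_effects_bland_altman(d, subj)
        assert (ba.loa_upper - ba.bias) == pytest.approx(ba.bias - ba.loa_lower, abs=1e-12)


class TestSummary:
    def test_summary_row_follows_table_schema(self):
        sm = pd.DataFrame({"mae": [3.0, 4.0, 5.0], "mape": [4.0, 5.0, 6.0]})
        vc = VarianceComponents(100.0, 25.0, 0.0, 80.0)
        ba = mixed_effects_bland_altman([1.0, 2.0, 1.5, 2.5], ["A", "A", "B", "B"])
        out = summarize_device("watch_01", "overall", sm, vc, ba)
        assert (out.mae_median, out.mae_q1, out.mae_q3) == (4.0, 3.5, 4.5)
        assert out.ccc == pytest.approx(0.8)
        assert out.n_sessions == 3
        assert out.loa_lower <= out.bias <= out.loa_upper

    def test_single_session_iqr_degenerates_to_value(self):
        sm = pd.DataFrame({"mae": [4.2], "mape": [5.1]})
        vc = VarianceComponents(50.0, 10.0, 1.0, 80.0)
        ba = mixed_effects_bland_altman([1.0, 2.0], ["A", "B"])
        out = summarize_device("d", "overall", sm, vc, ba)
        assert out.mae_median == out.mae_q1 == out.mae_q3 == 4.2

    def test_invalid_summary_invariants_rejected(self):
        with pytest.raises(ValueError):
            AgreementSummary("d", "overall", 4, 3.5, 4.5, 5, 4.5, 5.5,
                             ccc=1.2, bias=0, loa_lower=-1, loa_upper=1, n_sessions=1)
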