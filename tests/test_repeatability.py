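"""Bland–Altman, coefficient of repeatability, ranking and group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stochlung import study
from stochlung.repeatability import (bland_altman, bias_t_test,
                                     cr_from_summary, group_compare,
                                     rank_devices, rank_summary, sd_from_loa)


class TestBlandAltman:
    def test_identical_vectors_give_zero_everything(self):
        x = np.array([10.0, 12.0, 15.0, 9.0])
        ba = bland_altman(x, x)
        assert ba.bias == 0.0 and ba.sd_d == 0.0 and ba.cr == 0.0
        assert (ba.loa_low, ba.loa_high) == (0.0, 0.0)
        assert ba.p_value == 1.0

    def test_plus_minus_one_hand_arithmetic(self):
        # d = {+1, -1}: bias 0, sd sqrt(2), CR = 1.96*sqrt(1) = 1.96
        ba = bland_altman([1.0, 0.0], [0.0, 1.0])
        assert ba.bias == 0.0
        assert ba.sd_d == pytest.approx(np.sqrt(2.0))
        assert ba.loa_low == pytest.approx(-2.772, abs=1e-3)
        assert ba.loa_high == pytest.approx(2.772, abs=1e-3)
        assert ba.cr == pytest.approx(1.96)

    def test_published_foster_lung_row(self):
        # n=17, bias 0.80, sd reconstructed from LoA (-1.68, 3.28)
        sd = sd_from_loa(-1.68, 3.28)
        assert sd == pytest.approx(1.2653, abs=1e-4)
        assert cr_from_summary(0.80, sd, 17) == pytest.approx(2.87, abs=0.05)
        t, p = bias_t_test(0.80, sd, 17)
        assert p == pytest.approx(0.02, abs=0.005)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])
        with pytest.raises(ValueError):
            bland_altman([1.0, np.nan], [2.0, 1.0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=30),
           st.floats(-100, 100))
    def test_cr_identity_and_shift_invariance(self, diffs, shift):
        """1.96*RMS(d) equals 1.96*sqrt(bias^2 + sd^2 (n-1)/n), and the
        whole analysis is invariant to adding a constant to both vectors."""
        d = np.asarray(diffs)
        first = d  # second = 0
        ba = bland_altman(first, np.zeros_like(first))
        alt = cr_from_summary(ba.bias, ba.sd_d, ba.n)
        assert abs(ba.cr - alt) < 1e-12 * max(1.0, ba.cr)
        assert ba.loa_high - ba.loa_low == pytest.approx(2 * 1.96 * ba.sd_d, abs=1e-9)
        ba2 = bland_altman(first + shift, np.zeros_like(first) + shift)
        assert ba2.bias == pytest.approx(ba.bias, abs=1e-8)
        assert ba2.cr == pytest.approx(ba.cr, abs=1e-8)


class TestPublishedTableReconstruction:
    @pytest.mark.parametrize("row", study.REPEATABILITY_TABLE,
                             ids=lambda r: f"{r.group}-{r.site}-{r.device}")
    def test_cr_reconstructed_from_bias_and_loa(self, row):
        sd = sd_from_loa(row.loa_low, row.loa_high)
        assert cr_from_summary(row.bias, sd, row.n) == pytest.approx(
            row.cr, abs=0.1)


class TestRanking:
    def test_simple_order(self):
        ranks = rank_devices({"Foster_pMDI": 1.0, "Trimbow_pMDI": 2.0,
                              "Spiriva_Respimat": 3.0})
        assert ranks == {"Foster_pMDI": 1, "Trimbow_pMDI": 2,
                         "Spiriva_Respimat": 3}

    def test_tie_break_follows_device_order(self):
        ranks = rank_devices({"Spiriva_Respimat": 1.0, "Trimbow_pMDI": 1.0,
                              "Foster_pMDI": 1.0})
        assert ranks == {"Foster_pMDI": 1, "Trimbow_pMDI": 2,
                         "Spiriva_Respimat": 3}

    def test_relabeling_permutes_ranks(self):
        base = {"Foster_pMDI": 0.5, "Trimbow_pMDI": 2.0, "Spiriva_Respimat": 1.0}
        ranks = rank_devices(base)
        swapped = {"Foster_pMDI": 2.0, "Trimbow_pMDI": 0.5, "Spiriva_Respimat": 1.0}
        ranks_swapped = rank_devices(swapped)
        assert ranks_swapped["Trimbow_pMDI"] == ranks["Foster_pMDI"]
        assert ranks_swapped["Foster_pMDI"] == ranks["Trimbow_pMDI"]

    def test_each_subject_uses_each_rank_once(self):
        df = pd.DataFrame([
            {"group": "Control", "subject_id": "a", "device": d, "abs_diff": v}
            for d, v in [("Foster_pMDI", 0.1), ("Trimbow_pMDI", 3.0),
                         ("Spiriva_Respimat", 1.0)]])
        counts = rank_summary(df)
        assert sorted(counts["rank"]) == [1, 2, 3]
        assert (counts["count"] == 1).all()


class TestGroupCompare:
    def test_identical_groups_not_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 1, 20)
        res = group_compare({"a": x, "b": x.copy(), "c": x.copy()})
        assert res.p_value > 0.5

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)  # 10 SD shift
        res = group_compare({"a": a, "b": b})
        assert res.pairwise[("a", "b")] < 0.001

    def test_bonferroni_never_below_raw(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(i * 0.3, 1, 15) for i, g in enumerate("abc")}
        res = group_compare(groups, method="anova")
        from scipy import stats as sps
        for (g1, g2), p_adj in res.pairwise.items():
            praw = sps.ttest_ind(groups[g1], groups[g2]).pvalue
            assert p_adj >= praw - 1e-12

    def test_small_groups_force_nonparametric(self):
        res = group_compare({"a": [1.0, 2.0], "b": [2.0, 3.0, 4.0]})
        assert res.method == "kruskal"
        assert any("n<3" in w for w in res.warnings)

    def test_skewed_data_selects_kruskal(self):
        rng = np.random.default_rng(3)
        groups = {g: np.exp(rng.normal(0, 1.5, 25)) for g in "abc"}
        res = group_compare(groups)
        assert res.method == "kruskal"
        assert set(res.pairwise) == {("a", "b"), ("a", "c"), ("b", "c")}
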