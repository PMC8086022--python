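"""Group statistics: oracle equivalences, BH-FDR semantics, map behavior."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sstats

import sleeptopo as st
from sleeptopo.stats import _oneway_f_vec, difference_scores


def _random_groups(rng, k=3, n=(8, 10, 12)):
    return [rng.normal(i * 0.3, 1.0, size=n[i % len(n)]) for i in range(k)]


class TestOnewayAnova:
    def test_identical_groups_give_zero_F(self):
        g = [1.0, 2.0, 3.0]
        F, d1, d2, p = st.oneway_anova(g, g, g)
        assert F == 0.0 and p == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        groups = _random_groups(rng)
        F, _, _, p = st.oneway_anova(*groups)
        F_sp, p_sp = sstats.f_oneway(*groups)
        assert F == pytest.approx(F_sp, rel=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-9)

    def test_summary_form_equals_raw_form(self, rng):
        for _ in range(20):
            groups = _random_groups(rng)
            F_raw, d1, d2, p_raw = st.oneway_anova(*groups)
            F_sum, e1, e2, p_sum = st.anova_from_summary(
                [g.mean() for g in groups], [g.std(ddof=1) for g in groups],
                [len(g) for g in groups])
            assert F_sum == pytest.approx(F_raw, rel=1e-10)
            assert (d1, d2) == (e1, e2)
            assert p_sum == pytest.approx(p_raw, rel=1e-10)

    def test_two_group_F_equals_t_squared(self, rng):
        x1, x2 = rng.normal(size=12), rng.normal(0.5, 1.0, size=9)
        F, _, _, pF = st.oneway_anova(x1, x2)
        t, _, pt = st.ttest_unpaired(x1, x2)
        assert F == pytest.approx(t * t, rel=1e-10)
        assert pF == pytest.approx(pt, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            st.oneway_anova([1.0, 2.0])
        with pytest.raises(ValueError):
            st.oneway_anova([1.0], [2.0, 3.0])
        F, *_ = st.anova_from_summary([1.0, 2.0], [0.0, 0.0], [5, 5])
        assert math.isinf(F)  # zero within-variance, unequal means

    def test_vectorized_F_matches_scalar(self, rng):
        mats = [rng.normal(size=(10, 7)), rng.normal(size=(12, 7)),
                rng.normal(size=(9, 7))]
        F_vec, d1, d2, p_vec = _oneway_f_vec(mats)
        for j in range(7):
            F, e1, e2, p = st.oneway_anova(*[m[:, j] for m in mats])
            assert F_vec[j] == pytest.approx(F, rel=1e-12)
            assert p_vec[j] == pytest.approx(p, rel=1e-9)


class TestTTests:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        t, df, p = st.ttest_unpaired(x, x)
        assert t == 0.0 and df == 4 and p == 1.0

    def test_paired_matches_one_sample_oracle(self, rng):
        pre, post = rng.normal(size=15), rng.normal(0.3, 1.0, size=15)
        t, df, p = st.ttest_paired(pre, post)
        t_sp, p_sp = sstats.ttest_1samp(post - pre, 0.0)
        assert t == pytest.approx(t_sp, rel=1e-12) and df == 14
        assert p == pytest.approx(p_sp, rel=1e-9)

    def test_paired_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        t, _, p = st.ttest_paired(x, x)
        assert t == 0.0 and p == 1.0
        t, _, _ = st.ttest_paired(x, x + 2.0)  # constant shift, zero variance
        assert math.isinf(t) and t > 0
        with pytest.raises(ValueError, match="mismatch"):
            st.ttest_paired([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_sign_follows_mean_difference(self):
        t, _, _ = st.ttest_from_summary(10.0, 2.0, 20, 8.0, 2.0, 20)
        assert t > 0
        t, _, _ = st.ttest_from_summary(8.0, 2.0, 20, 10.0, 2.0, 20)
        assert t < 0


def _bh_bruteforce(p, q):
    """Literal step-up: largest k with p(k) <= k q / m."""
    p = np.asarray(p)
    order = np.sort(p)
    m = len(p)
    best = 0.0
    for k in range(1, m + 1):
        if order[k - 1] <= k * q / m:
            best = order[k - 1]
    return p <= best if best > 0 else np.zeros(m, bool), best


class TestBHFDR:
    def test_hand_examples(self):
        mask, thr = st.bh_fdr([0.2, 0.3, 0.4], q=0.05)
        assert not mask.any() and thr == 0.0
        mask, thr = st.bh_fdr([0.01, 0.02, 0.05], q=0.05)
        assert mask.all() and thr == 0.05

    @given(hst.lists(hst.floats(1e-8, 1.0), min_size=1, max_size=60),
           hst.floats(0.01, 0.3))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_bruteforce_step_up(self, pvals, q):
        mask, thr = st.bh_fdr(pvals, q)
        mask_bf, thr_bf = _bh_bruteforce(pvals, q)
        assert np.array_equal(mask, mask_bf) and thr == thr_bf

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(1e-6, 1.0, size=80)
        p[:10] = rng.uniform(1e-6, 1e-3, size=10)
        mask, _ = st.bh_fdr(p, 0.05)
        reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.array_equal(mask, reject)

    @given(hst.lists(hst.floats(1e-8, 1.0), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_q(self, pvals):
        """Lowering q never adds discoveries."""
        lo, _ = st.bh_fdr(pvals, 0.01)
        hi, _ = st.bh_fdr(pvals, 0.10)
        assert not np.any(lo & ~hi)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            st.bh_fdr([], 0.05)
        with pytest.raises(ValueError):
            st.bh_fdr([0.0, 0.5], 0.05)
        with pytest.raises(ValueError):
            st.bh_fdr([0.5], 1.5)


class TestAnovaMap:
    def test_mask_consistent_with_threshold(self, table50):
        maps = st.anova_map(table50, "NREM")
        for m in maps.values():
            e = m.entries
            assert np.array_equal(e["significant"],
                                  e["p"] <= m.fdr_threshold if m.fdr_threshold else
                                  np.zeros(len(e), bool))
            assert m.family_size == 19 * 5  # one family per state

    def test_missing_state_rejected(self, table50):
        with pytest.raises(ValueError, match="not present"):
            st.anova_map(table50, "NAP")

    def test_single_group_rejected(self, table50):
        sub = table50[table50["group"] == "AD"]
        with pytest.raises(ValueError, match="2 groups"):
            st.anova_map(sub, "NREM")

    def test_posthoc_only_at_significant_channels(self, table50):
        m = st.anova_map(table50, "NREM")["sigma"]
        assert set(m.posthoc["channel"]) == set(m.significant_channels)


class TestInteractionMap:
    def test_equals_mixed_model_interaction(self, table50):
        """Difference-score F reproduces the mixed-design interaction F."""
        import pingouin as pg
        sub = table50[(table50["band"] == "delta")
                      & table50["state"].isin(["PM_WAKE", "AM_WAKE"])
                      & (table50["channel"] == "F4")]
        imap = st.interaction_map(table50, band="delta")
        F_pkg = imap.entries.set_index("channel").loc["F4", "statistic"]
        aov = pg.mixed_anova(data=sub, dv="log10_power", within="state",
                             between="group", subject="subject")
        F_mixed = aov.loc[aov["Source"] == "Interaction", "F"].iloc[0]
        assert F_pkg == pytest.approx(F_mixed, abs=1e-8)

    def test_no_interaction_when_change_is_shared(self, rng):
        """Equal mean change in every group → interaction F near zero on average."""
        rows = []
        for i in range(60):
            g = ["AD", "MCI", "HC"][i % 3]
            pm = rng.normal()
            am = pm - 0.3 + 0.1 * rng.normal()  # same mean change in every group
            for state, val in (("PM_WAKE", pm), ("AM_WAKE", am)):
                rows.append({"subject": f"s{i}", "group": g, "state": state,
                             "channel": "Cz", "band": "delta",
                             "power_uv2": 10.0 ** val, "log10_power": val})
        table = pd.DataFrame(rows)
        imap = st.interaction_map(table, band="delta")
        assert not imap.entries["significant"].any()

    def test_subject_missing_session_excluded(self, table50, caplog):
        drop = table50["subject"].iloc[0]
        trimmed = table50[~((table50["subject"] == drop)
                            & (table50["state"] == "AM_WAKE"))]
        d = difference_scores(trimmed)
        assert drop not in d.index
        assert len(d) == 149
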