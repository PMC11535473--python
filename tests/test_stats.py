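"""ANOVA, Tukey HSD, specific rates, feed-window metric, GI."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.integrate import quad
from scipy.special import gamma as gamma_fn

from chosoft.core import CSV_COLUMNS, Channel, CultureTable
from chosoft.stats import (DegenerateInputError, anova_oneway, compare_models,
                           feed_window_difference, fold_change,
                           galactosylation_index, specific_rate, tukey_hsd)
from conftest import make_table


def studentized_range_sf_oracle(q, k, df):
    """Survival function of the studentized range by direct numeric
    integration of its classical double-integral representation."""
    def inner(s):
        def f(z):
            return sps.norm.pdf(z) * (sps.norm.cdf(z) - sps.norm.cdf(z - q * s)) ** (k - 1)
        val, _ = quad(f, -8, 8, limit=200)
        return k * val
    # s = chi/sqrt(df) with chi^2 ~ chi2(df)
    def outer(s):
        dens = (df ** (df / 2) / (2 ** (df / 2 - 1) * gamma_fn(df / 2))
                * s ** (df - 1) * np.exp(-df * s * s / 2))
        return dens * inner(s)
    cdf, _ = quad(outer, 1e-6, 8, limit=200)
    return 1.0 - cdf


class TestAnova:
    def test_hand_computed_f(self):
        F, dfb, dfw, p = anova_oneway([[1, 2, 3], [4, 5, 6]])
        assert F == pytest.approx(13.5)
        assert (dfb, dfw) == (1, 4)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(m, 1, n) for m, n in ((0, 5), (1, 7), (0.3, 6))]
        F, _, _, p = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_identical_constant_groups(self):
        F, _, _, p = anova_oneway([[2, 2], [2, 2, 2]])
        assert F == 0.0 and p == 1.0

    def test_null_p_values_uniform(self):
        """Identically distributed groups give uniform p-values (KS check)."""
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            ps.append(anova_oneway([r.normal(0, 1, 6) for _ in range(3)])[3])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], []])


class TestTukey:
    def test_two_group_identity_with_pooled_t(self):
        worst = 0.0
        for seed in range(100):
            r = np.random.default_rng(seed)
            a, b = r.normal(0, 1, 5), r.normal(0.4, 1.3, 8)
            p_t = sps.ttest_ind(a, b, equal_var=True).pvalue
            p_tk = tukey_hsd({"A": a, "B": b}).p_adj[0]
            worst = max(worst, abs(p_t - p_tk))
        assert worst < 1e-8

    def test_three_groups_match_numeric_oracle(self):
        rng = np.random.default_rng(12)
        groups = {"a": rng.normal(0, 1, 6), "b": rng.normal(1, 1, 6),
                  "c": rng.normal(0.5, 1, 6)}
        table = tukey_hsd(groups)
        n_tot = 18
        df = n_tot - 3
        msw = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df
        for _, row in table.iterrows():
            q = row.difference / np.sqrt(msw / 6)
            p_oracle = studentized_range_sf_oracle(q, 3, df)
            assert row.p_adj == pytest.approx(p_oracle, abs=1e-6)

    def test_matches_scipy_tukey(self, rng):
        a, b, c = (rng.normal(m, 1, 6) for m in (0, 1, 0.3))
        mine = np.sort(tukey_hsd({"a": a, "b": b, "c": c}).p_adj.to_numpy())
        ref = np.sort(sps.tukey_hsd(a, b, c).pvalue[np.triu_indices(3, 1)])
        np.testing.assert_allclose(mine, ref, atol=1e-10)

    def test_self_comparison_p_one(self):
        vals = [1.0, 2.0, 3.0]
        t = tukey_hsd({"x": vals, "x2": list(vals)})
        assert t.difference[0] == 0.0 and t.p_adj[0] == pytest.approx(1.0)

    def test_orientation_and_ordering(self, rng):
        groups = {k: rng.normal(m, 1, 5) for k, m in
                  zip("abcd", (0, 3, 1, 7))}
        t = tukey_hsd(groups)
        assert (t.difference >= 0).all()
        assert (t.difference.diff().dropna() <= 1e-12).all()
        assert ((t.lower_cl <= t.difference) & (t.difference <= t.upper_cl)).all()

    def test_p_monotone_in_difference(self):
        """At fixed SE and df, a larger difference gives a smaller p."""
        base = np.array([0.0, 0.1, -0.1, 0.05, -0.05])
        last = 1.1
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            t = tukey_hsd({"a": base, "b": base + shift})
            assert t.p_adj[0] <= last + 1e-12
            last = t.p_adj[0]

    def test_degenerate_variance_flagged(self):
        t = tukey_hsd({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert t.degenerate.all()
        assert t.p_adj[0] == 0.0


class TestSpecificRate:
    def test_constant_concentration_zero(self):
        t = np.array([0.0, 24, 48])
        assert specific_rate(t, [5, 5, 5], t, [1e6] * 3, 0, 48) == 0.0

    def test_linear_drop_closed_form(self):
        t = np.array([0.0, 24, 48])
        qs = specific_rate(t, [30, 25, 20], t, [2e6] * 3, 0, 48)
        assert qs == pytest.approx(-10 / (2e6 * 48))

    def test_doubling_xv_halves_rate(self):
        t = np.array([0.0, 48])
        q1 = specific_rate(t, [30, 20], t, [2e6] * 2, 0, 48)
        q2 = specific_rate(t, [30, 20], t, [4e6] * 2, 0, 48)
        assert q2 == pytest.approx(q1 / 2)

    def test_interior_points_on_linear_segment_invariant(self):
        t1 = np.array([0.0, 48])
        t2 = np.array([0.0, 12, 24, 36, 48])
        xv2 = 1e6 + t2 * 1e4   # linear VCD
        q_sparse = specific_rate(t1, [30, 20], t1, [1e6, 1e6 + 48e4], 0, 48)
        q_dense = specific_rate(t1, [30, 20], t2, xv2, 0, 48)
        assert q_dense == pytest.approx(q_sparse, rel=1e-12)

    def test_uncovered_window_rejected(self):
        t = np.array([0.0, 48])
        with pytest.raises(DegenerateInputError):
            specific_rate(t, [1, 2], t, [1e6, 1e6], 0, 96)


class TestFoldChange:
    def test_equal_rates(self):
        assert fold_change(-2e-5, -2e-5) == 1.0

    def test_printed_rate_pair(self):
        # ratio of two galactose-uptake rates measured across feed windows
        assert fold_change(-1.708e-5, -2.700e-5) == pytest.approx(1.5808, abs=1e-4)

    def test_reciprocity(self):
        assert (fold_change(-3.0, 2.0) * fold_change(2.0, -3.0)
                == pytest.approx(1.0))

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fold_change(0.0, 1.0)


class TestFeedWindowDifference:
    def test_identical_series_zero(self):
        t = [0, 10, 20]
        assert feed_window_difference(t, [1, 2, 3], t, [1, 2, 3],
                                      [(0, 10), (10, 20)]) == 0.0

    def test_direct_value(self):
        assert feed_window_difference([0, 10], [0, 1.5], [0, 10], [0, 1.0],
                                      [(0, 10)]) == pytest.approx(50.0)

    def test_offset_invariance(self):
        t = [0, 10, 20]
        a = feed_window_difference(t, [1, 2.5, 3], t, [1, 2, 3], [(0, 20)])
        b = feed_window_difference(t, [11, 12.5, 13], t, [7, 8, 9], [(0, 20)])
        assert a == pytest.approx(b)

    def test_zero_observed_increment_rejected(self):
        with pytest.raises(DegenerateInputError):
            feed_window_difference([0, 10], [0, 1], [0, 10], [2, 2], [(0, 10)])


class TestGalactosylationIndex:
    @pytest.mark.parametrize("g0,g1,g2,expected", [
        (100, 0, 0, 0.0),
        (0, 0, 100, 1.0),
        (50, 30, 20, 0.35),
        (0, 100, 0, 0.5),
    ])
    def test_values(self, g0, g1, g2, expected):
        assert galactosylation_index(g0, g1, g2) == pytest.approx(expected)

    def test_all_zero_undefined(self):
        with pytest.raises(DegenerateInputError):
            galactosylation_index(0, 0, 0)


def series_table(name, cond, times, values, channel="VCD", rep=1):
    return [(name, cond, rep, float(t), channel, float(v))
            for t, v in zip(times, values)]


class TestCompareModels:
    def make_sources(self, rng, offset=0.0):
        times = np.arange(0.0, 97.0, 24.0)
        base = 1e6 + 1e5 * times + 2e4 * rng.standard_normal(len(times))
        exp = make_table(series_table("e", "Validation", times, base))
        ident = make_table(series_table("m", "Validation", times, base + offset))
        return exp, ident, times, base

    def test_identical_model_p_one(self, rng):
        exp, ident, times, base = self.make_sources(rng)
        other = make_table(series_table(
            "o", "Validation", times, base * (1 + 0.2 * rng.standard_normal(len(times)))))
        rep = compare_models(exp, {"M": ident, "O": other}, [Channel.VCD])
        t = rep["VCD"]["tukey"]
        row = t[((t.level_a == "Exp") & (t.level_b == "M"))
                | ((t.level_a == "M") & (t.level_b == "Exp"))].iloc[0]
        assert row.p_adj == pytest.approx(1.0)

    def test_large_offset_detected(self, rng):
        exp, _, times, base = self.make_sources(rng)
        jitter = lambda: base + 3e4 * rng.standard_normal(len(times))
        shifted = make_table(series_table("s", "Validation", times,
                                          jitter() + 50 * np.std(base)))
        close = make_table(series_table("c", "Validation", times, jitter()))
        rep = compare_models(exp, {"S": shifted, "C": close}, [Channel.VCD])
        t = rep["VCD"]["tukey"]
        row = t[(t.level_a == "S") | (t.level_b == "S")].iloc[0]
        assert row.p_adj < 0.05

    def test_rows_sorted_by_descending_difference(self, rng):
        exp, ident, times, base = self.make_sources(rng, offset=0.0)
        m2 = make_table(series_table("m2", "Validation", times, base * 1.5))
        rep = compare_models(exp, {"M": ident, "M2": m2}, [Channel.VCD])
        d = rep["VCD"]["tukey"].difference
        assert (d.diff().dropna() <= 1e-9).all()

    def test_no_overlap_rejected(self, rng):
        times = np.arange(0.0, 97.0, 24.0)
        exp = make_table(series_table("e", "Validation", times, times + 1))
        m = make_table(series_table("m", "Validation", times + 7.0, times + 1))
        with pytest.raises(DegenerateInputError):
            compare_models(exp, {"M": m}, [Channel.VCD])

    def test_glycan_per_timepoint(self, rng):
        rows = []
        for rep_i in (1, 2, 3):
            for t in (72.0, 96.0):
                for name, v in (("G0F", 60), ("G1F", 30), ("G2F", 10)):
                    rows.append(("e", "Validation", rep_i, t, name,
                                 v + rng.normal(0, 1)))
        exp = make_table(rows)
        pred_rows = [r for r in rows]
        pred = make_table([("m", c, r, t, ch, v + 8 if ch == "G0F" else v)
                           for (_, c, r, t, ch, v) in rows])
        rep = compare_models(exp, {"M": pred}, [Channel.G0F])
        assert set(rep["G0F"].keys()) == {72.0, 96.0}
        p = rep["G0F"][72.0]["tukey"].p_adj[0]
        assert p < 0.05
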