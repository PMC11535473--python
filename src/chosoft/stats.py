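"""Model-vs-experiment evaluation harness.

One-way ANOVA with Tukey's HSD all-pairs comparison (Tukey-Kramer for
unequal group sizes), specific consumption/production rates over the
integral of viable cell density, fold changes, a feed-window trend-accuracy
metric, and the galactosylation index.

Caveat documented on purpose: "whole culture duration" comparisons treat
timepoints along one trajectory as independent observations.  The
autocorrelation this ignores inflates the nominal degrees of freedom; the
harness reproduces the convention rather than endorsing it, and replicate
construction (e.g. counting a pooled average as a third replicate) is left
to the caller.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Channel, CultureTable

__all__ = ["anova_oneway", "tukey_hsd", "specific_rate", "fold_change",
           "feed_window_difference", "galactosylation_index", "compare_models"]


class DegenerateInputError(ValueError):
    pass


def anova_oneway(groups):
    """Classical one-way ANOVA.

    Returns (F, df_between, df_within, p).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    n_total = sum(len(g) for g in groups)
    k = len(groups)
    df_b, df_w = k - 1, n_total - k
    if df_w < 1:
        raise ValueError("no residual degrees of freedom")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0:
        if ssb == 0:
            return 0.0, df_b, df_w, 1.0
        return float("inf"), df_b, df_w, 0.0
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return float(F), df_b, df_w, p


def tukey_hsd(groups: dict, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD comparison table.

    ``groups`` maps level name -> values.  Unequal group sizes use the
    Tukey-Kramer standard error sqrt(MSW*(1/n_a + 1/n_b)/1) with the pooled
    within-group mean square; p-values come from the studentized-range
    distribution with k levels and the pooled df.  Rows are oriented so the
    difference (mean_a - mean_b) is >= 0 and sorted by descending
    |difference|.

    Columns: level_a, level_b, difference, std_err_dif, lower_cl, upper_cl,
    p_adj (the printed layout of all-pairs mean-comparison tables).
    """
    names = list(groups.keys())
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 levels")
    n_total = sum(len(v) for v in arrs.values())
    df_w = n_total - k
    if df_w < 1:
        raise ValueError("no residual degrees of freedom")
    msw = sum(((v - v.mean()) ** 2).sum() for v in arrs.values()) / df_w
    degenerate = msw <= 0
    rows = []
    for a, b in itertools.combinations(names, 2):
        ga, gb = arrs[a], arrs[b]
        diff = ga.mean() - gb.mean()
        if diff < 0:
            a, b, ga, gb, diff = b, a, gb, ga, -diff
        if degenerate:
            se = 0.0
            p = 1.0 if diff == 0 else 0.0
            lcl = ucl = diff
        else:
            # Tukey-Kramer: SE of the difference, q statistic uses SE/sqrt(2)
            se = np.sqrt(msw * (1.0 / len(ga) + 1.0 / len(gb)))
            q = diff / (se / np.sqrt(2.0))
            p = float(sps.studentized_range.sf(q, k, df_w))
            qcrit = sps.studentized_range.ppf(1 - alpha, k, df_w)
            half = qcrit * se / np.sqrt(2.0)
            lcl, ucl = diff - half, diff + half
        rows.append({"level_a": a, "level_b": b, "difference": diff,
                     "std_err_dif": se, "lower_cl": lcl, "upper_cl": ucl,
                     "p_adj": min(max(p, 0.0), 1.0),
                     "degenerate": degenerate})
    table = pd.DataFrame(rows).sort_values("difference", ascending=False,
                                           kind="mergesort")
    return table.reset_index(drop=True)


def specific_rate(times_conc, conc, times_xv, xv, t1: float, t2: float) -> float:
    """Specific rate qs = (C(t2) - C(t1)) / integral_t1^t2 Xv dt.

    Concentration and viable cell density series are linearly interpolated
    where needed; the IVCD integral uses the trapezoid rule on the available
    points (plus the interpolated endpoints).  Consumption gives a negative
    qs.  Units: mM/(cell/mL * h) when conc is mM and xv is cells/mL.
    """
    times_conc = np.asarray(times_conc, dtype=float)
    conc = np.asarray(conc, dtype=float)
    times_xv = np.asarray(times_xv, dtype=float)
    xv = np.asarray(xv, dtype=float)
    if t2 <= t1:
        raise ValueError("t2 must be > t1")
    for t, ts, what in ((t1, times_conc, "conc"), (t2, times_conc, "conc"),
                        (t1, times_xv, "VCD"), (t2, times_xv, "VCD")):
        if t < ts.min() - 1e-9 or t > ts.max() + 1e-9:
            raise DegenerateInputError(f"{what} series does not cover {t} h")
    c1 = np.interp(t1, times_conc, conc)
    c2 = np.interp(t2, times_conc, conc)
    inner = (times_xv > t1) & (times_xv < t2)
    ts = np.concatenate([[t1], times_xv[inner], [t2]])
    vs = np.concatenate([[np.interp(t1, times_xv, xv)], xv[inner],
                         [np.interp(t2, times_xv, xv)]])
    ivcd = np.trapezoid(vs, ts)
    if ivcd <= 0:
        raise DegenerateInputError("non-positive integral viable cell density")
    return float((c2 - c1) / ivcd)


def fold_change(qs_a: float, qs_b: float) -> float:
    """|qs_b| / |qs_a| — magnitude ratio of two specific rates."""
    if qs_a == 0:
        raise ZeroDivisionError("reference rate is zero")
    return abs(qs_b) / abs(qs_a)


def feed_window_difference(times_pred, pred, times_obs, obs, windows) -> float:
    """Mean absolute percent difference of per-window trend increments.

    Per window (t_start, t_end): Delta = value(t_end) - value(t_start) for
    each series, and the percent difference is
    100 * |Delta_pred - Delta_obs| / |Delta_obs|.  Offsetting both series by
    a constant leaves the metric unchanged.
    """
    times_pred = np.asarray(times_pred, dtype=float)
    pred = np.asarray(pred, dtype=float)
    times_obs = np.asarray(times_obs, dtype=float)
    obs = np.asarray(obs, dtype=float)
    vals = []
    for (t0, t1) in windows:
        for ts, what in ((times_pred, "pred"), (times_obs, "obs")):
            if t0 < ts.min() - 1e-9 or t1 > ts.max() + 1e-9:
                raise DegenerateInputError(
                    f"{what} series does not cover window ({t0}, {t1})")
        d_pred = np.interp(t1, times_pred, pred) - np.interp(t0, times_pred, pred)
        d_obs = np.interp(t1, times_obs, obs) - np.interp(t0, times_obs, obs)
        if d_obs == 0:
            raise DegenerateInputError(f"observed increment zero in ({t0}, {t1})")
        vals.append(100.0 * abs(d_pred - d_obs) / abs(d_obs))
    return float(np.mean(vals))


def galactosylation_index(G0F: float, G1F: float, G2F: float) -> float:
    """Fraction of occupied galactosylation sites under the two-site model:
    GI = (0.5*G1F + G2F) / (G0F + G1F + G2F), in [0, 1]."""
    if min(G0F, G1F, G2F) < 0:
        raise ValueError("glycan fractions must be non-negative")
    total = G0F + G1F + G2F
    if total <= 0:
        raise DegenerateInputError("all glycan fractions zero: GI undefined")
    return float((0.5 * G1F + G2F) / total)


def _series(table: CultureTable, ch: Channel):
    sub = table.df[(table.df["channel"] == ch.name)
                   & table.df["value"].notna()]
    grp = sub.groupby("time_h")["value"].mean().sort_index()
    return grp.index.to_numpy(dtype=float), grp.to_numpy(dtype=float)


def compare_models(experimental: CultureTable, predictions: dict,
                   variables: list, timepoints=None, alpha: float = 0.05):
    """ANOVA + Tukey HSD comparison of experiment and model predictions.

    ``predictions`` maps model name -> prediction CultureTable.  For
    whole-duration variables (VCD, titer, NSDs) each source contributes one
    value per shared timepoint and a single Tukey table is emitted per
    variable.  For glycan fraction channels, one analysis is run per shared
    timepoint across sources using replicate values where available.

    Returns {channel_name: {"anova": (F, df_b, df_w, p), "tukey": table}}
    or, for glycans, {channel_name: {time: {...}}}.
    """
    report = {}
    sources = {"Exp": experimental, **predictions}
    for ch in variables:
        if ch.is_glycan:
            per_time = {}
            times_sets = []
            for tbl in sources.values():
                t, _ = _series(tbl, ch)
                times_sets.append(set(np.round(t, 6)))
            shared = sorted(set.intersection(*times_sets)) if times_sets else []
            use = [t for t in shared if timepoints is None or t in timepoints]
            for t in use:
                groups = {}
                for name, tbl in sources.items():
                    sub = tbl.df[(tbl.df["channel"] == ch.name)
                                 & np.isclose(tbl.df["time_h"], t)
                                 & tbl.df["value"].notna()]
                    if len(sub):
                        groups[name] = sub["value"].to_numpy(dtype=float)
                if len(groups) >= 2 and sum(len(v) for v in groups.values()) > len(groups):
                    per_time[t] = {
                        "anova": anova_oneway(list(groups.values())),
                        "tukey": tukey_hsd(groups, alpha=alpha),
                    }
            report[ch.name] = per_time
        else:
            series = {name: _series(tbl, ch) for name, tbl in sources.items()}
            shared = set.intersection(*[set(np.round(t, 6)) for t, _ in series.values()])
            shared = sorted(shared)
            if len(shared) < 2:
                raise DegenerateInputError(
                    f"fewer than 2 overlapping timepoints for {ch.name}")
            groups = {}
            for name, (t, v) in series.items():
                mask = np.isin(np.round(t, 6), shared)
                groups[name] = v[mask]
            report[ch.name] = {
                "anova": anova_oneway(list(groups.values())),
                "tukey": tukey_hsd(groups, alpha=alpha),
            }
    return report
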