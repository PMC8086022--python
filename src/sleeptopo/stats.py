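"""Channel-wise group statistics with Benjamini-Hochberg FDR.

One-way fixed-effects ANOVA (raw-data and summary-statistics forms),
pooled-variance Student t tests (unpaired, summary and paired), the BH
step-up procedure, and the map-level operations that apply them per
channel over the band-power table:

* :func:`anova_map` — omnibus group ANOVA per channel, FDR-corrected
  over all channels × bands of one behavioral state, with post-hoc
  pairwise t tests gated on omnibus significance.
* :func:`interaction_map` — the Group × Time-of-day interaction for a
  two-level within factor (evening vs morning wakefulness), computed
  as a one-way ANOVA on per-subject difference scores, which is exactly
  the mixed-design interaction F when the within factor has 2 levels.

The FDR threshold reported in a :class:`StatMap` is the data-dependent
BH cutoff — the largest p-value declared significant — matching the
convention of reporting a single "p <= threshold" per family of maps.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scalar tests

def oneway_anova(*groups: Sequence[float]) -> tuple[float, int, int, float]:
    """Classical one-way fixed-effects ANOVA.

    Returns ``(F, df_between, df_within, p)``. With all groups constant
    and equal, F is defined as 0 (p = 1).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValueError(f"group {i} has n={a.size} < 2")
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    N = int(ns.sum())
    grand = float(np.concatenate(arrays).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_b, df_w = k - 1, N - k
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, df_b, df_w, 1.0
        logger.warning("zero within-group variance with unequal means: F = inf")
        return math.inf, df_b, df_w, 0.0
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sstats.f.sf(F, df_b, df_w))
    return F, df_b, df_w, max(p, np.finfo(float).tiny)


def anova_from_summary(means: Sequence[float], sds: Sequence[float],
                       ns: Sequence[int]) -> tuple[float, int, int, float]:
    """One-way ANOVA from per-group (mean, SD, n) summary statistics.

    SSB = sum n_i (m_i - m̄)² with m̄ the n-weighted grand mean;
    SSW = sum (n_i - 1) sd_i². Identical to :func:`oneway_anova` on the
    underlying raw data.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (len(means) == len(sds) == len(ns)) or len(means) < 2:
        raise ValueError("means, sds, ns must have equal length >= 2")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    if np.any(sds < 0):
        raise ValueError("standard deviations must be >= 0")
    k = len(means)
    N = float(ns.sum())
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds ** 2).sum())
    df_b, df_w = k - 1, int(N - k)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, df_b, df_w, 1.0
        logger.warning("SSW = 0 with SSB > 0: F = inf")
        return math.inf, df_b, df_w, 0.0
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sstats.f.sf(F, df_b, df_w))
    return F, df_b, df_w, max(p, np.finfo(float).tiny)


def ttest_unpaired(x1: Sequence[float], x2: Sequence[float]) -> tuple[float, int, float]:
    """Pooled-variance two-sample Student t test (two-sided)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("need n >= 2 per group")
    return ttest_from_summary(float(x1.mean()), float(x1.std(ddof=1)), x1.size,
                              float(x2.mean()), float(x2.std(ddof=1)), x2.size)


def ttest_from_summary(m1: float, sd1: float, n1: int,
                       m2: float, sd2: float, n2: int) -> tuple[float, int, float]:
    """Pooled-variance t test from summary statistics; df = n1 + n2 - 2.

    The sign of t follows the direction of ``m1 - m2``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    if sp2 == 0.0:
        if m1 == m2:
            return 0.0, df, 1.0
        return math.copysign(math.inf, m1 - m2), df, 0.0
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(2.0 * sstats.t.sf(abs(t), df))
    return t, df, max(p, np.finfo(float).tiny)


def ttest_paired(x_pre: Sequence[float], x_post: Sequence[float]) -> tuple[float, int, float]:
    """Paired t test: one-sample t on post - pre differences; df = n - 1."""
    x_pre = np.asarray(x_pre, dtype=float)
    x_post = np.asarray(x_post, dtype=float)
    if x_pre.shape != x_post.shape:
        raise ValueError(f"length mismatch: {x_pre.size} vs {x_post.size}")
    if x_pre.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = x_post - x_pre
    df = d.size - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, d.mean()), df, 0.0
    t = float(d.mean() / (sd / math.sqrt(d.size)))
    p = float(2.0 * sstats.t.sf(abs(t), df))
    return t, df, max(p, np.finfo(float).tiny)


def bh_fdr(pvals: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over one family of p-values.

    Returns ``(mask, threshold)`` where threshold is the largest p(k)
    with p(k) <= k·q/m (0.0 and an all-false mask when no k qualifies)
    and the mask marks p <= threshold.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.sort(p)
    crit = np.arange(1, m + 1) * q / m
    passing = np.nonzero(order <= crit)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    threshold = float(order[passing[-1]])
    return p <= threshold, threshold


# ---------------------------------------------------------------------------
# vectorized one-way F over many channels at once (same algebra as
# oneway_anova; used by the map operations)

def _oneway_f_vec(groups: Sequence[np.ndarray]) -> tuple[np.ndarray, int, int, np.ndarray]:
    """F and p per column for a list of (n_i × n_tests) group matrices."""
    k = len(groups)
    ns = np.array([g.shape[0] for g in groups])
    N = int(ns.sum())
    means = np.stack([g.mean(axis=0) for g in groups])  # (k, n_tests)
    grand = (ns[:, None] * means).sum(axis=0) / N
    ssb = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ssw = np.stack([((g - m) ** 2).sum(axis=0) for g, m in zip(groups, means)]).sum(axis=0)
    df_b, df_w = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    F = np.where((ssw == 0) & (ssb == 0), 0.0, F)
    p = sstats.f.sf(F, df_b, df_w)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return F, df_b, df_w, p


# ---------------------------------------------------------------------------
# statistical maps

@dataclass
class StatMap:
    """Per-channel test results for one analysis family member.

    ``entries`` has one row per channel: statistic, df1, df2 (NaN for t
    maps), p, significant. ``family_id`` names the FDR family the
    channel tests were corrected in; ``fdr_threshold`` is the family's
    data-dependent BH cutoff.
    """

    analysis_id: str
    state: str
    band: str
    statistic_kind: str  # "F" or "t"
    entries: pd.DataFrame
    q: float
    fdr_threshold: float
    family_id: str
    family_size: int
    posthoc: pd.DataFrame | None = None

    @property
    def significant_channels(self) -> list[str]:
        return list(self.entries.loc[self.entries["significant"], "channel"])

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    def sidecar(self) -> dict:
        return {
            "analysis_id": self.analysis_id,
            "state": self.state,
            "band": self.band,
            "statistic_kind": self.statistic_kind,
            "q": self.q,
            "fdr_threshold": self.fdr_threshold,
            "family_id": self.family_id,
            "family_size": self.family_size,
        }


def _pivot_state(table: pd.DataFrame, state: str, band: str) -> pd.DataFrame:
    sub = table[(table["state"] == state) & (table["band"] == band)]
    return sub.pivot(index="subject", columns="channel", values="log10_power")


def _group_of(table: pd.DataFrame) -> pd.Series:
    return table.drop_duplicates("subject").set_index("subject")["group"]


def anova_map(table: pd.DataFrame, state: str, q: float = 0.05,
              bands: Sequence[str] | None = None,
              group_order: Sequence[str] = ("AD", "MCI", "HC"),
              posthoc_alpha: float = 0.05) -> dict[str, StatMap]:
    """Channel-wise one-way group ANOVA maps for one state, FDR per state.

    The FDR family is all channels × bands within the state (one map per
    band, one shared BH threshold). Post-hoc pairwise pooled-variance t
    tests are run only at channels whose omnibus test survives FDR.
    Subjects missing any channel of a band are dropped listwise for
    that band.
    """
    if state not in set(table["state"]):
        raise ValueError(f"state {state!r} not present in table")
    bands = list(bands) if bands is not None else list(dict.fromkeys(table["band"]))
    groups_by_subject = _group_of(table)
    present = [g for g in group_order if g in set(groups_by_subject)]
    if len(present) < 2:
        raise ValueError(f"need >= 2 groups, found {present}")

    per_band: dict[str, dict] = {}
    all_p: list[np.ndarray] = []
    for band in bands:
        wide = _pivot_state(table, state, band).dropna(axis=0)
        grp = groups_by_subject.loc[wide.index]
        mats = [wide[grp == g].to_numpy() for g in present]
        ns = [m.shape[0] for m in mats]
        if min(ns) < 2:
            raise ValueError(f"state {state}, band {band}: a group has n < 2")
        F, df_b, df_w, p = _oneway_f_vec(mats)
        per_band[band] = {"wide": wide, "grp": grp, "F": F,
                          "df": (df_b, df_w), "p": p}
        all_p.append(p)
        logger.info("anova_map %s/%s: n per group %s", state, band,
                    dict(zip(present, ns)))

    family_p = np.concatenate(all_p)
    mask, threshold = bh_fdr(family_p, q)
    family_id = f"anova:{state}"

    maps: dict[str, StatMap] = {}
    offset = 0
    for band in bands:
        d = per_band[band]
        chans = list(d["wide"].columns)
        n_ch = len(chans)
        sig = mask[offset : offset + n_ch]
        offset += n_ch
        entries = pd.DataFrame({
            "channel": chans,
            "statistic": d["F"],
            "df1": d["df"][0], "df2": d["df"][1],
            "p": d["p"], "significant": sig,
        })
        posthoc = _posthoc_pairwise(d["wide"], d["grp"], present,
                                    np.array(chans)[sig], posthoc_alpha)
        maps[band] = StatMap(
            analysis_id=f"anova:{state}:{band}", state=state, band=band,
            statistic_kind="F", entries=entries, q=q, fdr_threshold=threshold,
            family_id=family_id, family_size=int(family_p.size), posthoc=posthoc,
        )
    return maps


def _posthoc_pairwise(wide: pd.DataFrame, grp: pd.Series, present: Sequence[str],
                      channels: Sequence[str], alpha: float) -> pd.DataFrame:
    rows = []
    for ch in channels:
        for g1, g2 in itertools.combinations(present, 2):
            t, df, p = ttest_unpaired(wide.loc[grp == g1, ch], wide.loc[grp == g2, ch])
            rows.append({"channel": ch, "group1": g1, "group2": g2,
                         "t": t, "df": df, "p": p, "significant": p <= alpha})
    return pd.DataFrame(rows, columns=["channel", "group1", "group2",
                                       "t", "df", "p", "significant"])


def difference_scores(table: pd.DataFrame, band: str = "delta",
                      within: tuple[str, str] = ("PM_WAKE", "AM_WAKE")) -> pd.DataFrame:
    """Per-subject (second - first) log10-power difference per channel.

    Subjects missing either session are excluded listwise with a logged
    warning. Returns a subjects × channels frame plus a 'group' column.
    """
    pre, post = within
    wide_pre = _pivot_state(table, pre, band)
    wide_post = _pivot_state(table, post, band)
    common = wide_pre.dropna().index.intersection(wide_post.dropna().index)
    dropped = sorted(set(wide_pre.index) ^ set(wide_post.index))
    if dropped:
        logger.warning("difference_scores: excluding %d subject(s) missing a "
                       "session: %s", len(dropped), dropped)
    diff = wide_post.loc[common] - wide_pre.loc[common]
    diff.insert(0, "group", _group_of(table).loc[common])
    return diff


def interaction_map(table: pd.DataFrame, band: str = "delta",
                    within: tuple[str, str] = ("PM_WAKE", "AM_WAKE"),
                    q: float = 0.05,
                    group_order: Sequence[str] = ("AD", "MCI", "HC"),
                    posthoc_alpha: float = 0.05) -> StatMap:
    """Group × Time-of-day interaction map for a 2-level within factor.

    One-way ANOVA across groups on per-subject difference scores
    (e.g. AM − PM log10 delta power) per channel — algebraically equal
    to the mixed-design interaction F when the within factor has two
    levels. FDR across channels. Post-hoc: paired t per group (PM vs
    AM) and unpaired t between groups on the difference scores, at
    channels surviving FDR.
    """
    diff = difference_scores(table, band=band, within=within)
    grp = diff.pop("group")
    present = [g for g in group_order if g in set(grp)]
    if len(present) < 2:
        raise ValueError(f"need >= 2 groups, found {present}")
    mats = [diff[grp == g].to_numpy() for g in present]
    F, df_b, df_w, p = _oneway_f_vec(mats)
    mask, threshold = bh_fdr(p, q)
    chans = list(diff.columns)
    entries = pd.DataFrame({
        "channel": chans, "statistic": F, "df1": df_b, "df2": df_w,
        "p": p, "significant": mask,
    })

    sig_ch = list(np.array(chans)[mask])
    rows = []
    for ch in sig_ch:
        for g in present:
            x = diff.loc[grp == g, ch]
            t, df, pt = ttest_paired(np.zeros(len(x)), x)  # H0: mean change 0
            rows.append({"channel": ch, "contrast": f"{g}: {within[1]} vs {within[0]}",
                         "t": t, "df": df, "p": pt, "significant": pt <= posthoc_alpha})
        for g1, g2 in itertools.combinations(present, 2):
            t, df, pt = ttest_unpaired(diff.loc[grp == g1, ch], diff.loc[grp == g2, ch])
            rows.append({"channel": ch, "contrast": f"{g1} vs {g2} (change)",
                         "t": t, "df": df, "p": pt, "significant": pt <= posthoc_alpha})
    posthoc = pd.DataFrame(rows, columns=["channel", "contrast", "t", "df", "p",
                                          "significant"])
    return StatMap(
        analysis_id=f"interaction:{within[0]}-{within[1]}:{band}",
        state=f"{within[0]}-{within[1]}", band=band, statistic_kind="F",
        entries=entries, q=q, fdr_threshold=threshold,
        family_id=f"interaction:{band}", family_size=len(chans), posthoc=posthoc,
    )
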