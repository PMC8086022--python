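"""Bundled reference summary statistics.

Sleep-macrostructure group summaries (mean, SD, n = 50 per group) for
clinical AD / MCI / HC cohorts, as printed in the polysomnographic
literature this package's analyses emulate. They feed the
summary-statistics ANOVA/t utilities and the ``replicate-macro``
CLI subcommand, which recomputes the inferential statistics from these
summaries alone.
"""

from __future__ import annotations

import pandas as pd

_N = 50

#: variable → group → (mean, sd); durations in minutes, percentages of TST
REFERENCE_MACRO_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "sol_min": {"AD": (35.86, 42.32), "MCI": (23.89, 17.76), "HC": (16.52, 16.35)},
    "rem_latency_min": {"AD": (110.20, 80.74), "MCI": (117.93, 89.19), "HC": (104.86, 59.77)},
    "waso_min": {"AD": (82.63, 50.75), "MCI": (88.45, 51.58), "HC": (78.94, 47.71)},
    "n1_pct": {"AD": (9.94, 9.46), "MCI": (8.73, 6.25), "HC": (6.62, 5.12)},
    "n2_pct": {"AD": (74.28, 9.52), "MCI": (74.44, 9.20), "HC": (76.54, 5.86)},
    "n3_pct": {"AD": (0.20, 0.48), "MCI": (0.12, 0.23), "HC": (0.65, 1.16)},
    "rem_pct": {"AD": (15.58, 9.16), "MCI": (16.71, 7.67), "HC": (16.19, 5.56)},
    "tbt_min": {"AD": (389.05, 58.19), "MCI": (411.07, 91.02), "HC": (385.47, 44.72)},
    "tst_min": {"AD": (270.09, 76.30), "MCI": (284.52, 67.30), "HC": (290.72, 60.32)},
    "sei_pct": {"AD": (69.27, 15.78), "MCI": (70.38, 15.79), "HC": (75.51, 13.23)},
    "isa_count": {"AD": (18.98, 11.45), "MCI": (19.18, 9.45), "HC": (20.20, 9.44)},
}


def reference_macro_summary() -> pd.DataFrame:
    """Tidy frame of the bundled summaries: variable, group, mean, sd, n."""
    rows = []
    for var, groups in REFERENCE_MACRO_SUMMARY.items():
        for g, (m, sd) in groups.items():
            rows.append({"variable": var, "group": g, "mean": m, "sd": sd, "n": _N})
    return pd.DataFrame(rows)


def recompute_macro_inference(summary: pd.DataFrame | None = None,
                              posthoc_alpha: float = 0.05) -> pd.DataFrame:
    """Recompute one-way ANOVA F (and post-hoc t where significant) per variable.

    Returns a frame with columns variable, F, df1, df2, p and, for
    variables whose omnibus ANOVA reaches ``posthoc_alpha``, the three
    pairwise pooled-variance t statistics.
    """
    from .stats import anova_from_summary, ttest_from_summary

    df = summary if summary is not None else reference_macro_summary()
    out = []
    for var, sub in df.groupby("variable", sort=False):
        sub = sub.set_index("group")
        order = ["AD", "MCI", "HC"]
        means = [sub.loc[g, "mean"] for g in order]
        sds = [sub.loc[g, "sd"] for g in order]
        ns = [int(sub.loc[g, "n"]) for g in order]
        F, d1, d2, p = anova_from_summary(means, sds, ns)
        row: dict = {"variable": var, "F": F, "df1": d1, "df2": d2, "p": p}
        if p <= posthoc_alpha:
            for (i, j), label in (((0, 1), "t_ad_mci"), ((0, 2), "t_ad_hc"),
                                  ((1, 2), "t_mci_hc")):
                t, _, pt = ttest_from_summary(means[i], sds[i], ns[i],
                                              means[j], sds[j], ns[j])
                row[label] = t
                row[label + "_p"] = pt
        out.append(row)
    return pd.DataFrame(out)
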