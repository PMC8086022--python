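"""EEG slowing index and overnight delta-power change.

The slowing index is the ratio of slow to fast absolute band power,

    (delta + theta) / (alpha + sigma + beta),

computed on linear (not log) power, so it is dimensionless, strictly
positive, invariant to overall power scaling, and increases when the
spectrum shifts toward low frequencies. The overnight delta change is
AM log10 delta power minus PM log10 delta power per channel; negative
values mean delta activity decreased across the night (the healthy,
sleep-restored pattern).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .bands import FAST_BANDS, SLOW_BANDS

logger = logging.getLogger(__name__)


def slowing_index(powers: Mapping[str, float],
                  slow: tuple[str, ...] = SLOW_BANDS,
                  fast: tuple[str, ...] = FAST_BANDS) -> float:
    """(delta + theta) / (alpha + sigma + beta) on linear power in µV²."""
    missing = [b for b in (*slow, *fast) if b not in powers]
    if missing:
        raise ValueError(f"missing band power(s): {missing}")
    bad = [b for b in (*slow, *fast) if not powers[b] > 0]
    if bad:
        raise ValueError(f"non-positive band power(s): {bad}")
    num = sum(powers[b] for b in slow)
    den = sum(powers[b] for b in fast)
    return num / den


def slowing_map(table: pd.DataFrame, state: str,
                slow: tuple[str, ...] = SLOW_BANDS,
                fast: tuple[str, ...] = FAST_BANDS) -> pd.DataFrame:
    """Slowing index per subject × channel for one behavioral state.

    Returns a tidy frame (subject, group, channel, slowing_index). A
    subject × channel with any constituent band missing is set to NaN
    and logged, never silently dropped.
    """
    sub = table[table["state"] == state]
    if sub.empty:
        raise ValueError(f"state {state!r} not present in table")
    wide = sub.pivot(index=["subject", "channel"], columns="band", values="power_uv2")
    missing_any = wide[list(slow + fast)].isna().any(axis=1)
    if missing_any.any():
        logger.warning("slowing_map %s: %d subject×channel cells missing a band",
                       state, int(missing_any.sum()))
    num = wide[list(slow)].sum(axis=1, min_count=len(slow))
    den = wide[list(fast)].sum(axis=1, min_count=len(fast))
    out = (num / den).rename("slowing_index").reset_index()
    groups = sub.drop_duplicates("subject").set_index("subject")["group"]
    out.insert(1, "group", out["subject"].map(groups))
    out.insert(2, "state", state)
    return out


def overnight_delta_change(table: pd.DataFrame, band: str = "delta",
                           sessions: tuple[str, str] = ("PM_WAKE", "AM_WAKE")
                           ) -> pd.DataFrame:
    """AM − PM log10 band power per subject × channel (tidy frame).

    Subjects missing either wake session get NaN with a logged warning.
    """
    pre, post = sessions
    sub = table[table["band"] == band]
    wide = {
        s: sub[sub["state"] == s].pivot(index="subject", columns="channel",
                                        values="log10_power")
        for s in (pre, post)
    }
    subjects = wide[pre].index.union(wide[post].index)
    incomplete = sorted(set(subjects) - (set(wide[pre].dropna().index)
                                         & set(wide[post].dropna().index)))
    if incomplete:
        logger.warning("overnight_delta_change: %d subject(s) missing a wake "
                       "session: %s", len(incomplete), incomplete)
    diff = wide[post].reindex(subjects) - wide[pre].reindex(subjects)
    out = diff.stack(future_stack=True).rename("delta_change").reset_index()
    groups = table.drop_duplicates("subject").set_index("subject")["group"]
    out.insert(1, "group", out["subject"].map(groups))
    return out


def representative_series(tidy: pd.DataFrame, channel: str,
                          value: str) -> pd.Series:
    """Per-subject values of one column at a single representative channel.

    Used to extract e.g. the F4 overnight delta change or the O1 REM
    slowing index as the seed variable of a correlation map.
    """
    sub = tidy[tidy["channel"] == channel]
    if sub.empty:
        raise ValueError(f"channel {channel!r} not present")
    return sub.set_index("subject")[value]
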