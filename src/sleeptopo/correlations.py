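"""Correlation topographies and the Fisher-z severity trend.

Pearson and Spearman correlations with two-sided p-values (t transform
with n−2 df), channel-wise correlation maps between a per-subject seed
scalar (e.g. the F4 overnight delta change, the O1 REM slowing index,
or MMSE) and a per-channel variable, BH-FDR over the map family, and
the descriptive linear trend of Fisher-z-transformed correlations
across disease severity (HC=0, MCI=1, AD=2).
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .stats import bh_fdr

logger = logging.getLogger(__name__)


def _corr_p(r: float, n: int) -> float:
    """Two-sided p for a correlation via the t transform, df = n − 2."""
    if abs(r) >= 1.0:
        return np.finfo(float).tiny
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return max(float(2.0 * sstats.t.sf(abs(t), n - 2)), np.finfo(float).tiny)


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson r with two-sided p and n after pairwise-complete filtering."""
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 complete pairs, have {n}")
    for name, v in (("x", x), ("y", y)):
        if np.std(v) == 0:
            raise ValueError(f"zero variance in {name}")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return r, _corr_p(r, n), n


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Spearman rho = Pearson on average ranks (ties averaged)."""
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 complete pairs, have {n}")
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    for name, v in (("x", rx), ("y", ry)):
        if np.std(v) == 0:
            raise ValueError(f"zero variance in ranks of {name}")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    return rho, _corr_p(rho, n), n


class CorrMap:
    """Per-channel correlations of a seed scalar against a channel variable.

    ``entries``: one row per channel (r, p, n, significant); the BH
    family may span several maps computed together (shared threshold).
    """

    def __init__(self, analysis_id: str, entries: pd.DataFrame, q: float,
                 fdr_threshold: float, family_id: str, family_size: int,
                 method: str = "pearson") -> None:
        self.analysis_id = analysis_id
        self.entries = entries
        self.q = q
        self.fdr_threshold = fdr_threshold
        self.family_id = family_id
        self.family_size = family_size
        self.method = method

    @property
    def significant_channels(self) -> list[str]:
        return list(self.entries.loc[self.entries["significant"], "channel"])

    def r_by_channel(self) -> pd.Series:
        return self.entries.set_index("channel")["r"]

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    def sidecar(self) -> dict:
        return {"analysis_id": self.analysis_id, "method": self.method,
                "q": self.q, "fdr_threshold": self.fdr_threshold,
                "family_id": self.family_id, "family_size": self.family_size}


def _channel_corrs(seed: pd.Series, wide: pd.DataFrame, min_n: int = 3
                   ) -> pd.DataFrame:
    rows = []
    for ch in wide.columns:
        y = wide[ch]
        common = seed.index.intersection(y.index)
        x = seed.loc[common].to_numpy(dtype=float)
        yv = y.loc[common].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(yv)
        if keep.sum() < min_n:
            logger.warning("channel %s: only %d complete pairs, skipping",
                           ch, int(keep.sum()))
            rows.append({"channel": ch, "r": np.nan, "p": np.nan, "n": int(keep.sum())})
            continue
        r, p, n = pearson(x[keep], yv[keep])
        rows.append({"channel": ch, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def correlation_map(seed: pd.Series, targets: Mapping[str, pd.DataFrame],
                    q: float = 0.05, family_id: str = "corr",
                    ) -> dict[str, CorrMap]:
    """Channel-wise Pearson maps of one seed against several target frames.

    ``targets`` maps an analysis label (e.g. "NREM:sigma") to a
    subjects × channels frame; all maps passed together form one BH
    family with a shared threshold, mirroring a single FDR cutoff per
    figure-level family.
    """
    per_label = {label: _channel_corrs(seed, wide) for label, wide in targets.items()}
    pool = pd.concat(per_label.values())
    valid = pool["p"].notna().to_numpy()
    if not valid.any():
        raise ValueError("no channel had enough complete pairs")
    mask_valid, threshold = bh_fdr(pool.loc[valid, "p"].to_numpy(), q)
    sig = np.zeros(len(pool), dtype=bool)
    sig[valid] = mask_valid
    pool["significant"] = sig

    out: dict[str, CorrMap] = {}
    offset = 0
    for label, df in per_label.items():
        chunk = pool.iloc[offset : offset + len(df)].reset_index(drop=True)
        offset += len(df)
        out[label] = CorrMap(analysis_id=f"{family_id}:{label}", entries=chunk,
                             q=q, fdr_threshold=threshold, family_id=family_id,
                             family_size=int(valid.sum()))
    return out


def fisher_z_trend(r_by_group: Mapping[str, Sequence[float]] | pd.DataFrame,
                   group_order: Sequence[str] = ("HC", "MCI", "AD")
                   ) -> pd.DataFrame:
    """OLS trend of atanh(r) on the severity ordinal HC=0, MCI=1, AD=2.

    ``r_by_group`` maps group → per-channel correlation vector (or a
    channels-indexed DataFrame with one column per group). Returns a
    frame (channel, beta, r_squared). Reported descriptively, without
    p-values. A constant triple gives beta = 0 and r_squared = 0 (the
    0/0 convention for a zero-variance fit).
    """
    if isinstance(r_by_group, pd.DataFrame):
        df = r_by_group[list(group_order)]
        channels = list(df.index)
        R = df.to_numpy(dtype=float)
    else:
        cols = [np.asarray(r_by_group[g], dtype=float) for g in group_order]
        n = {len(c) for c in cols}
        if len(n) != 1:
            raise ValueError("per-group r vectors must have equal length")
        R = np.stack(cols, axis=1)
        channels = list(range(R.shape[0]))
    if np.any(np.abs(R) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher z transform")
    Z = np.arctanh(R)  # (n_channels, 3)
    x = np.arange(len(group_order), dtype=float)
    xc = x - x.mean()
    beta = (Z * xc).sum(axis=1) / (xc ** 2).sum()
    fit = Z.mean(axis=1, keepdims=True) + beta[:, None] * xc
    ss_res = ((Z - fit) ** 2).sum(axis=1)
    ss_tot = ((Z - Z.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.where(ss_tot == 0.0, 0.0, r2)
    return pd.DataFrame({"channel": channels, "beta": beta,
                         "r_squared": np.clip(r2, 0.0, 1.0)})


def mmse_correlates(mmse: pd.Series, eeg_features: Mapping[str, pd.DataFrame],
                    macro_scalars: Mapping[str, pd.Series] | None = None,
                    q: float = 0.05) -> tuple[dict[str, CorrMap], pd.DataFrame]:
    """Correlations between cognition (MMSE) and EEG/macrostructure indices.

    Pearson maps (one BH family across all EEG feature maps) for the
    channel-resolved EEG indices, pooled across groups; Spearman for
    ordinal macrostructure scalars such as sleep-onset latency and N3%.
    Returns ``(maps, scalar_frame)``.
    """
    if np.std(mmse.to_numpy(dtype=float)) == 0:
        raise ValueError("MMSE has zero variance")
    maps = correlation_map(mmse, eeg_features, q=q, family_id="mmse")
    rows = []
    for name, series in (macro_scalars or {}).items():
        common = mmse.index.intersection(series.index)
        rho, p, n = spearman(mmse.loc[common], series.loc[common])
        rows.append({"variable": name, "rho": rho, "p": p, "n": n})
    scalars = pd.DataFrame(rows, columns=["variable", "rho", "p", "n"])
    return maps, scalars
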