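"""Hypnogram container and sleep-macrostructure scoring.

A hypnogram is a sequence of 30-s (by default) scoring epochs, each
labelled W, N1, N2, N3 or R, together with lights-off/lights-on markers
delimiting the in-bed period. ``score_macrostructure`` derives the
standard polysomnographic summary variables: sleep-onset latency (SOL),
REM latency, wake after sleep onset (WASO), stage percentages of total
sleep time (TST), total bed time (TBT), sleep efficiency index (SEI)
and the number of intra-sleep awakenings (ISA).

Scoring conventions (stated here because operational definitions vary
between laboratories):

* Sleep onset is the first epoch scored as any sleep stage — a single
  N1 epoch counts.
* WASO counts W epochs strictly between sleep onset and the last sleep
  epoch; terminal wake (after the final sleep epoch) is excluded.
* ISA is the number of maximal runs of one or more W epochs inside
  that same interval.
* Percentages are of TST. Metrics that are undefined for a given record
  (e.g. SOL when no sleep occurred) are returned as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")
SLEEP_STAGES: frozenset[str] = frozenset({"N1", "N2", "N3", "R"})


@dataclass(frozen=True)
class Hypnogram:
    """Staged hypnogram with an in-bed window.

    Parameters
    ----------
    stages
        Ordered stage codes, one per scoring epoch, each in
        {W, N1, N2, N3, R}.
    epoch_len_s
        Seconds per scoring epoch (default 30).
    lights_off_idx, lights_on_idx
        Epoch indices delimiting the in-bed period ``[off, on)``.
        Default: the whole record.
    """

    stages: tuple[str, ...]
    epoch_len_s: float = 30.0
    lights_off_idx: int = 0
    lights_on_idx: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        if self.lights_on_idx is None:
            object.__setattr__(self, "lights_on_idx", len(self.stages))
        bad = sorted({s for s in self.stages} - set(STAGES))
        if bad:
            raise ValueError(f"invalid stage code(s) {bad}; allowed: {list(STAGES)}")
        if self.epoch_len_s <= 0:
            raise ValueError("epoch_len_s must be positive")
        if not (0 <= self.lights_off_idx < self.lights_on_idx <= len(self.stages)):
            raise ValueError(
                "require 0 <= lights_off_idx < lights_on_idx <= n_epochs; got "
                f"off={self.lights_off_idx}, on={self.lights_on_idx}, n={len(self.stages)}"
            )

    @property
    def in_bed(self) -> tuple[str, ...]:
        return self.stages[self.lights_off_idx : self.lights_on_idx]

    @property
    def epoch_min(self) -> float:
        return self.epoch_len_s / 60.0


@dataclass(frozen=True)
class MacroMetrics:
    """Sleep macrostructure summary for one night (all durations in minutes)."""

    sol_min: float
    rem_latency_min: float
    waso_min: float
    n1_pct: float
    n2_pct: float
    n3_pct: float
    rem_pct: float
    tbt_min: float
    tst_min: float
    sei_pct: float
    isa_count: float

    #: column order used by TSV export; matches the conventional PSG table
    FIELDS = (
        "sol_min", "rem_latency_min", "waso_min",
        "n1_pct", "n2_pct", "n3_pct", "rem_pct",
        "tbt_min", "tst_min", "sei_pct", "isa_count",
    )

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FIELDS}


def score_macrostructure(h: Hypnogram) -> MacroMetrics:
    """Score the standard macrostructure variables from a hypnogram.

    All quantities are computed on the in-bed window
    ``[lights_off_idx, lights_on_idx)``. Undefined values (no sleep in
    the record) come back as NaN.
    """
    epochs = h.in_bed
    epoch_min = h.epoch_min
    tbt_min = len(epochs) * epoch_min

    sleep_idx = [i for i, s in enumerate(epochs) if s in SLEEP_STAGES]
    if not sleep_idx:
        return MacroMetrics(
            sol_min=math.nan, rem_latency_min=math.nan, waso_min=math.nan,
            n1_pct=math.nan, n2_pct=math.nan, n3_pct=math.nan, rem_pct=math.nan,
            tbt_min=tbt_min, tst_min=0.0, sei_pct=0.0, isa_count=math.nan,
        )

    onset, last = sleep_idx[0], sleep_idx[-1]
    sol_min = onset * epoch_min

    counts = {s: 0 for s in STAGES}
    for s in epochs:
        counts[s] += 1
    tst_min = sum(counts[s] for s in SLEEP_STAGES) * epoch_min

    # W epochs strictly inside the sleep period; terminal wake excluded
    waso_epochs = sum(1 for s in epochs[onset : last + 1] if s == "W")
    waso_min = waso_epochs * epoch_min

    # maximal runs of W inside the sleep period
    isa = 0
    in_run = False
    for s in epochs[onset : last + 1]:
        if s == "W" and not in_run:
            isa += 1
            in_run = True
        elif s != "W":
            in_run = False

    rem_after_onset = [i for i in sleep_idx if epochs[i] == "R"]
    rem_latency_min = (rem_after_onset[0] - onset) * epoch_min if rem_after_onset else math.nan

    pct = {s: 100.0 * counts[s] * epoch_min / tst_min for s in ("N1", "N2", "N3", "R")}
    sei_pct = 100.0 * tst_min / tbt_min

    return MacroMetrics(
        sol_min=sol_min,
        rem_latency_min=rem_latency_min,
        waso_min=waso_min,
        n1_pct=pct["N1"], n2_pct=pct["N2"], n3_pct=pct["N3"], rem_pct=pct["R"],
        tbt_min=tbt_min, tst_min=tst_min, sei_pct=sei_pct, isa_count=float(isa),
    )


# ---------------------------------------------------------------------------
# I/O

def read_hypnogram_csv(path: str | Path, epoch_len_s: float = 30.0,
                       lights_off_idx: int = 0,
                       lights_on_idx: int | None = None) -> Hypnogram:
    """Read a hypnogram from a two-column CSV (epoch_index, stage)."""
    df = pd.read_csv(path)
    if not {"epoch_index", "stage"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'epoch_index' and 'stage'")
    df = df.sort_values("epoch_index")
    return Hypnogram(tuple(df["stage"].astype(str)), epoch_len_s=epoch_len_s,
                     lights_off_idx=lights_off_idx, lights_on_idx=lights_on_idx)


def write_hypnogram_csv(h: Hypnogram, path: str | Path) -> None:
    pd.DataFrame({"epoch_index": range(len(h.stages)), "stage": h.stages}).to_csv(
        path, index=False
    )


def macro_table(hypnograms: dict[str, Hypnogram]) -> pd.DataFrame:
    """Score a set of hypnograms into one row per subject."""
    rows = []
    for sid, h in hypnograms.items():
        row = {"subject": sid}
        row.update(score_macrostructure(h).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def write_macro_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
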