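"""End-to-end analysis pipeline.

simulate (or load) → macrostructure scoring → band-power table →
group statistical maps → overnight-change interaction and its sleep
correlates → slowing maps → wake–REM slowing correlations and severity
trend → MMSE correlates → report bundle on disk.

Every run is fully determined by (config, seed) and writes a JSON
manifest recording both.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import DEFAULT_BANDS, BandScheme
from .correlations import correlation_map, fisher_z_trend, mmse_correlates, pearson
from .hypnogram import macro_table, write_macro_tsv
from .montage import MONTAGE_1020, validate_channels
from .simulate import GROUPS, CohortDataset, CohortSpec, generate_cohort
from .slowing import overnight_delta_change, representative_series, slowing_map
from .spectral import WelchParams, build_band_power_table
from .stats import StatMap, anova_map, interaction_map, oneway_anova

logger = logging.getLogger(__name__)

WAKE_SESSIONS = ("PM_WAKE", "AM_WAKE")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run depends on besides the seed."""

    out_dir: str = "sleeptopo_out"
    mode: str = "table"  # "table" (band powers from the model) or "signal"
    n_per_group: int = 50
    q: float = 0.05
    delta_change_channel: str = "F4"  # seed channel for overnight-change correlations
    rem_slowing_channel: str = "O1"   # seed channel for wake–REM slowing maps
    welch_window_s: float = 4.0
    welch_overlap: float = 0.5
    input_dir: str | None = None      # analyze an existing cohort instead of simulating

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.mode not in ("table", "signal"):
            raise ValueError(f"mode must be 'table' or 'signal', got {self.mode!r}")
        validate_channels([self.delta_change_channel, self.rem_slowing_channel])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _write_statmap(m: StatMap, out: Path, stem: str) -> None:
    m.to_tsv(out / f"{stem}.tsv")
    (out / f"{stem}.json").write_text(json.dumps(m.sidecar(), indent=2))
    if m.posthoc is not None and len(m.posthoc):
        m.posthoc.to_csv(out / f"{stem}_posthoc.tsv", sep="\t", index=False)


def _slowing_wide(table: pd.DataFrame, state: str) -> pd.DataFrame:
    """log10 slowing index as subjects × channels (log for symmetric stats)."""
    tidy = slowing_map(table, state)
    wide = tidy.pivot(index="subject", columns="channel", values="slowing_index")
    return np.log10(wide)


def run_pipeline(config: PipelineConfig, seed: int) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a summary dict (also written as ``summary.json``) with the
    key quantities: macrostructure ANOVAs, FDR thresholds and
    significant-channel lists per map, representative correlations and
    the severity trend of the wake–REM slowing correlation.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = CohortSpec(n_per_group=config.n_per_group)
    if config.input_dir is not None:
        cohort = _load_cohort(Path(config.input_dir), spec, seed)
    else:
        cohort = generate_cohort(spec, seed=seed, mode=config.mode)
        cohort.to_disk(out / "cohort")

    summary: dict = {"seed": seed, "version": __version__,
                     "config": dataclasses.asdict(config)}

    # 1. sleep macrostructure + group ANOVAs
    macro = macro_table(cohort.hypnograms)
    groups = cohort.subjects_frame().set_index("id")["group"]
    macro.insert(1, "group", macro["subject"].map(groups))
    write_macro_tsv(macro, out / "macro.tsv")
    macro_stats = []
    for var in ("sol_min", "rem_latency_min", "waso_min", "n1_pct", "n2_pct",
                "n3_pct", "rem_pct", "tbt_min", "tst_min", "sei_pct", "isa_count"):
        vals = [macro.loc[macro["group"] == g, var].dropna() for g in GROUPS]
        if min(len(v) for v in vals) < 2:
            continue
        F, d1, d2, p = oneway_anova(*vals)
        macro_stats.append({"variable": var, "F": F, "df1": d1, "df2": d2, "p": p})
    macro_anova = pd.DataFrame(macro_stats)
    macro_anova.to_csv(out / "macro_anova.tsv", sep="\t", index=False)
    summary["macro_anova"] = macro_anova.to_dict("records")

    # 2. band-power table
    welch = WelchParams(config.welch_window_s, config.welch_overlap)
    table = build_band_power_table(cohort, DEFAULT_BANDS, welch)
    table.to_csv(out / "bandpower.tsv", sep="\t", index=False)

    # 3. state × band ANOVA maps, FDR per state
    summary["anova_maps"] = {}
    for state in ("NREM", "REM", "PM_WAKE", "AM_WAKE"):
        maps = anova_map(table, state, q=config.q)
        for band, m in maps.items():
            _write_statmap(m, out, f"anova_{state}_{band}")
        summary["anova_maps"][state] = {
            "fdr_threshold": next(iter(maps.values())).fdr_threshold,
            "significant": {b: m.significant_channels for b, m in maps.items()},
        }

    # 4. Group × Time-of-day interaction on waking delta + sleep correlates
    imap = interaction_map(table, band="delta", within=WAKE_SESSIONS, q=config.q)
    _write_statmap(imap, out, "interaction_delta")
    summary["interaction"] = {"fdr_threshold": imap.fdr_threshold,
                              "significant": imap.significant_channels}

    change = overnight_delta_change(table, sessions=WAKE_SESSIONS)
    change.to_csv(out / "overnight_delta.tsv", sep="\t", index=False)
    seed_change = representative_series(change, config.delta_change_channel,
                                        "delta_change")
    ad_ids = groups[groups == "AD"].index
    targets = {}
    for state in ("NREM", "REM"):
        for band in DEFAULT_BANDS.names:
            wide = (table[(table["state"] == state) & (table["band"] == band)]
                    .pivot(index="subject", columns="channel", values="log10_power"))
            targets[f"{state}:{band}"] = wide.loc[wide.index.intersection(ad_ids)]
    corr_sleep = correlation_map(seed_change.loc[seed_change.index.intersection(ad_ids)],
                                 targets, q=config.q, family_id="delta_change_AD")
    for label, cm in corr_sleep.items():
        cm.to_tsv(out / f"corr_change_{label.replace(':', '_')}.tsv")
    summary["change_sleep_corr_AD"] = {
        label: {"significant": cm.significant_channels,
                "min_r": float(cm.entries["r"].min())}
        for label, cm in corr_sleep.items()
    }

    # 5. slowing maps + group ANOVAs on them
    slow_frames = {}
    for state in ("PM_WAKE", "REM", "AM_WAKE"):
        tidy = slowing_map(table, state)
        tidy.to_csv(out / f"slowing_{state}.tsv", sep="\t", index=False)
        slow_frames[state] = tidy
    summary["slowing_anova"] = {}
    for state, tidy in slow_frames.items():
        pseudo = tidy.rename(columns={"slowing_index": "log10_power"}).copy()
        pseudo["log10_power"] = np.log10(pseudo["log10_power"])
        pseudo["band"] = "slowing"
        m = anova_map(pseudo, state, q=config.q, bands=["slowing"])["slowing"]
        _write_statmap(m, out, f"slowing_anova_{state}")
        summary["slowing_anova"][state] = {"fdr_threshold": m.fdr_threshold,
                                           "significant": m.significant_channels}

    # 6. wake–REM slowing correlations per group + Fisher-z severity trend
    rem_seed_all = representative_series(slow_frames["REM"],
                                         config.rem_slowing_channel, "slowing_index")
    rem_seed_all = np.log10(rem_seed_all)
    trend_input: dict[str, pd.DataFrame] = {}
    summary["wake_rem_corr"] = {}
    for session in ("PM_WAKE", "AM_WAKE"):
        wake_wide = _slowing_wide(table, session)
        r_cols = {}
        for g in GROUPS:
            ids = groups[groups == g].index
            sub = wake_wide.loc[wake_wide.index.intersection(ids)]
            cms = correlation_map(rem_seed_all.loc[rem_seed_all.index.intersection(ids)],
                                  {session: sub}, q=config.q,
                                  family_id=f"wake_rem:{g}:{session}")
            cm = cms[session]
            cm.to_tsv(out / f"corr_wakerem_{g}_{session}.tsv")
            r_cols[g] = cm.r_by_channel()
            summary["wake_rem_corr"][f"{g}:{session}"] = {
                "mean_r": float(cm.entries["r"].mean()),
                "significant": cm.significant_channels,
            }
        trend = fisher_z_trend(pd.DataFrame(r_cols))
        trend.to_csv(out / f"trend_{session}.tsv", sep="\t", index=False)
        trend_input[session] = trend
        summary["wake_rem_corr"][f"trend:{session}"] = {
            "mean_beta": float(trend["beta"].mean()),
            "mean_r2": float(trend["r_squared"].mean()),
        }

    # 7. MMSE correlates
    mmse = cohort.subjects_frame().set_index("id")["mmse"].astype(float)
    mmse.index.name = "subject"
    nrem_sigma = (table[(table["state"] == "NREM") & (table["band"] == "sigma")]
                  .pivot(index="subject", columns="channel", values="log10_power"))
    eeg_feats = {
        "nrem_sigma": nrem_sigma,
        "rem_slowing": _slowing_wide(table, "REM"),
        "pm_slowing": _slowing_wide(table, "PM_WAKE"),
        "am_slowing": _slowing_wide(table, "AM_WAKE"),
    }
    macro_scalars = {
        "sol_min": macro.set_index("subject")["sol_min"],
        "n3_pct": macro.set_index("subject")["n3_pct"],
    }
    maps, scalars = mmse_correlates(mmse, eeg_feats, macro_scalars, q=config.q)
    for label, cm in maps.items():
        cm.to_tsv(out / f"corr_mmse_{label}.tsv")
    scalars.to_csv(out / "corr_mmse_macro.tsv", sep="\t", index=False)
    summary["mmse_corr"] = {
        label: {"mean_r": float(cm.entries["r"].mean()),
                "n_significant": int(cm.entries["significant"].sum())}
        for label, cm in maps.items()
    }
    summary["mmse_macro"] = scalars.to_dict("records")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    manifest = {"seed": seed, "version": __version__,
                "config": dataclasses.asdict(config)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return summary


def _load_cohort(path: Path, spec: CohortSpec, seed: int) -> CohortDataset:
    """Load a previously exported table-mode cohort directory."""
    from .hypnogram import read_hypnogram_csv
    from .simulate import SubjectRecord
    from .spectral import read_bandpower_tsv

    subj = pd.read_csv(path / "subjects.tsv", sep="\t")
    subjects = [SubjectRecord(r.id, r.group, int(r.mmse)) for r in subj.itertuples()]
    hyps = {s.id: read_hypnogram_csv(path / "hypnograms" / f"{s.id}.csv")
            for s in subjects}
    table = read_bandpower_tsv(path / "bandpower.tsv")
    return CohortDataset(subjects=subjects, hypnograms=hyps, signals=None,
                         band_powers=table, spec=spec, seed=seed)
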