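"""Synthetic wake/sleep EEG cohorts with planted group structure.

Generates cohorts of AD / MCI / HC subjects — hypnograms, state-resolved
multichannel EEG (or directly the band-power table in fast "table-only"
mode), and MMSE scores — carrying the statistical structure the
downstream analyses look for:

* longer sleep-onset latency and less N3 in the clinical groups;
* frontotemporal delta elevation in wakefulness and REM sleep, and
  posterior alpha/sigma/beta reduction in NREM/REM sleep, ordered
  AD > MCI > HC;
* an overnight (AM − PM) drop in waking delta power that is present in
  HC, attenuated in MCI and absent in AD, coupled (in AD) to the
  subject's sleep high-frequency activity;
* within-group correlation between waking and REM-sleep EEG slowing
  that strengthens with disease severity;
* MMSE decreasing with the planted slowing burden.

The model behind every band-power cell is log-normal:

    log10 P(subj, state, ch, band) = base(state, band)
        + regional offset(state, band, ch)
        + planted effect(state, band, ch) × severity_i / 2
        + spectral-tilt latent (REM / wake slowing)
        + sleep high-frequency latent (alpha/sigma/beta in sleep)
        + subject×state×band offset + channel noise

where severity_i is a per-subject latent with group means HC = 0,
MCI = 1, AD = 2, so a planted amplitude a is the mean AD − HC contrast
and MCI sits halfway. Morning-wake delta is the subject's evening value
plus a group-dependent overnight change, which makes the Group × Time
interaction exact by construction.

In signal mode each state is synthesized as a stationary sum of
independent band-limited Gaussian noise components, one per band, each
scaled so its variance equals the subject's target band power.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BandScheme, DEFAULT_BANDS, FAST_BANDS, SLOW_BANDS
from .hypnogram import Hypnogram, write_hypnogram_csv
from .montage import MONTAGE_1020, REGIONS
from .spectral import MultichannelSignal, write_bandpower_tsv

GROUPS: tuple[str, ...] = ("AD", "MCI", "HC")
#: severity ordinal underlying the planted effect sizes
GROUP_SEVERITY: dict[str, float] = {"HC": 0.0, "MCI": 1.0, "AD": 2.0}
STATES: tuple[str, ...] = ("PM_WAKE", "NREM", "REM", "AM_WAKE")
SLEEP_STATES: tuple[str, ...] = ("NREM", "REM")
WAKE_STATES: tuple[str, ...] = ("PM_WAKE", "AM_WAKE")


# ---------------------------------------------------------------------------
# spec dataclasses

@dataclass(frozen=True)
class PlantedEffect:
    """A topographic group effect: mean AD − HC log10-power contrast."""

    state: str
    band: str
    channels: tuple[str, ...]
    amplitude: float  # log10 units; sign gives direction (AD relative to HC)


@dataclass(frozen=True)
class HypnogramParams:
    """Markov-chain parameters for one group's hypnograms.

    ``sleep_stage_probs`` is the stationary stage distribution among
    sleep epochs (each sleep epoch is drawn i.i.d. from it, so expected
    stage percentages equal it exactly). ``p_onset`` is the per-epoch
    wake→sleep probability during the latency phase, giving expected
    sleep-onset latency = epoch_min / p_onset. ``p_awakening`` is the
    per-epoch sleep→wake probability; ``p_wake_persist`` the W→W
    probability of intra-sleep wake runs.
    """

    p_onset: float
    sleep_stage_probs: Mapping[str, float]
    p_awakening: float = 0.035
    p_wake_persist: float = 0.885

    def __post_init__(self) -> None:
        for name in ("p_onset", "p_awakening", "p_wake_persist"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        probs = dict(self.sleep_stage_probs)
        bad = set(probs) - {"N1", "N2", "N3", "R"}
        if bad:
            raise ValueError(f"sleep_stage_probs has invalid stages: {sorted(bad)}")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"sleep_stage_probs rows must sum to 1 (got {total!r})"
            )
        if any(p < 0 for p in probs.values()):
            raise ValueError("sleep_stage_probs must be non-negative")


def _stage_probs(n1_pct: float, n2_pct: float, n3_pct: float, rem_pct: float
                 ) -> dict[str, float]:
    tot = n1_pct + n2_pct + n3_pct + rem_pct
    return {"N1": n1_pct / tot, "N2": n2_pct / tot,
            "N3": n3_pct / tot, "R": rem_pct / tot}


#: per-group macrostructure parameters of the emulated clinical cohorts
#: (sleep-onset latency in min, stage % of TST, total bed time in min)
DEFAULT_SOL_PARAMS: dict[str, tuple[float, float]] = {
    "AD": (35.86, 42.32), "MCI": (23.89, 17.76), "HC": (16.52, 16.35),
}
DEFAULT_STAGE_PCTS: dict[str, dict[str, float]] = {
    "AD": _stage_probs(9.94, 74.28, 0.20, 15.58),
    "MCI": _stage_probs(8.73, 74.44, 0.12, 16.71),
    "HC": _stage_probs(6.62, 76.54, 0.65, 16.19),
}
DEFAULT_N3_PCT_PARAMS: dict[str, tuple[float, float]] = {
    "AD": (0.20, 0.48), "MCI": (0.12, 0.23), "HC": (0.65, 1.16),
}
DEFAULT_TBT_PARAMS: dict[str, tuple[float, float]] = {
    "AD": (389.05, 58.19), "MCI": (411.07, 91.02), "HC": (385.47, 44.72),
}

#: baseline log10 band power (µV²) per state × band for an elderly scalp EEG
DEFAULT_BASE_LOG10: dict[tuple[str, str], float] = {
    ("PM_WAKE", "delta"): 1.30, ("PM_WAKE", "theta"): 0.90,
    ("PM_WAKE", "alpha"): 1.10, ("PM_WAKE", "sigma"): 0.50,
    ("PM_WAKE", "beta"): 0.40,
    ("AM_WAKE", "delta"): 1.30, ("AM_WAKE", "theta"): 0.90,
    ("AM_WAKE", "alpha"): 1.10, ("AM_WAKE", "sigma"): 0.50,
    ("AM_WAKE", "beta"): 0.40,
    ("NREM", "delta"): 2.30, ("NREM", "theta"): 1.60,
    ("NREM", "alpha"): 1.20, ("NREM", "sigma"): 1.30,
    ("NREM", "beta"): 0.70,
    ("REM", "delta"): 1.50, ("REM", "theta"): 1.10,
    ("REM", "alpha"): 0.90, ("REM", "sigma"): 0.50,
    ("REM", "beta"): 0.50,
}

#: posterior alpha dominance during wakefulness and REM
DEFAULT_REGIONAL_OFFSETS: tuple[tuple[str, str, tuple[str, ...], float], ...] = (
    ("PM_WAKE", "alpha", REGIONS["posterior"], 0.30),
    ("AM_WAKE", "alpha", REGIONS["posterior"], 0.30),
    ("REM", "alpha", REGIONS["posterior"], 0.20),
)

#: the topographic group effects the analyses are expected to recover
DEFAULT_EFFECTS: tuple[PlantedEffect, ...] = (
    # NREM: left-temporal alpha and posterior sigma reduction
    PlantedEffect("NREM", "alpha", ("T3", "T5"), -0.30),
    PlantedEffect("NREM", "sigma", REGIONS["posterior"], -0.30),
    # REM: frontotemporal slowing, posterior fast-activity loss, plus a
    # scalp-wide tilt (REM slowing carries the strongest severity signal)
    PlantedEffect("REM", "delta", REGIONS["frontotemporal"], 0.30),
    PlantedEffect("REM", "alpha", REGIONS["temporo_occipital"], -0.30),
    PlantedEffect("REM", "sigma", REGIONS["temporo_occipital"], -0.30),
    PlantedEffect("REM", "beta", REGIONS["temporo_occipital"], -0.30),
    PlantedEffect("REM", "delta", MONTAGE_1020, 0.12),
    PlantedEffect("REM", "theta", MONTAGE_1020, 0.12),
    PlantedEffect("REM", "alpha", MONTAGE_1020, -0.12),
    PlantedEffect("REM", "sigma", MONTAGE_1020, -0.12),
    PlantedEffect("REM", "beta", MONTAGE_1020, -0.12),
    # evening wake: prefrontal/right-frontotemporal delta, right occipital alpha
    PlantedEffect("PM_WAKE", "delta", ("Fp1", "Fp2", "F4", "F8", "T4"), 0.30),
    PlantedEffect("PM_WAKE", "alpha", ("O2",), -0.30),
    # weak scalp-wide wake spectral tilt with severity: per band it stays
    # mostly below the FDR threshold, but the 5-band slowing ratio
    # aggregates it into a widespread group difference
    PlantedEffect("PM_WAKE", "delta", MONTAGE_1020, 0.07),
    PlantedEffect("PM_WAKE", "theta", MONTAGE_1020, 0.07),
    PlantedEffect("PM_WAKE", "alpha", MONTAGE_1020, -0.07),
    PlantedEffect("PM_WAKE", "sigma", MONTAGE_1020, -0.07),
    PlantedEffect("PM_WAKE", "beta", MONTAGE_1020, -0.07),
    PlantedEffect("AM_WAKE", "theta", MONTAGE_1020, 0.07),
    PlantedEffect("AM_WAKE", "alpha", MONTAGE_1020, -0.07),
    PlantedEffect("AM_WAKE", "sigma", MONTAGE_1020, -0.07),
    PlantedEffect("AM_WAKE", "beta", MONTAGE_1020, -0.07),
    # (morning delta inherits the evening pattern through the overnight-change
    # model, so no AM_WAKE delta entry appears here)
)

#: overnight AM − PM change in waking log10 delta power at the
#: frontal-central interaction cluster: preserved in HC, fading with severity
DEFAULT_OVERNIGHT_DROP: dict[str, float] = {"HC": -0.25, "MCI": -0.12, "AD": 0.0}
#: change shared by all groups outside the interaction cluster
DEFAULT_COMMON_DROP: float = -0.10
#: slope of the AD-specific coupling between the overnight change and the
#: sleep high-frequency latent (negative r: more sleep fast activity, larger drop)
DEFAULT_CHANGE_H_SLOPE: dict[str, float] = {"HC": 0.0, "MCI": 0.04, "AD": 0.18}

#: within-group correlation between the wake and REM spectral-tilt latents,
#: increasing with severity (drives the wake–REM slowing correlation trend)
DEFAULT_TILT_RHO: dict[str, float] = {"HC": 0.55, "MCI": 0.80, "AD": 0.95}


@dataclass(frozen=True)
class MMSECoupling:
    """MMSE = round(clip(base − sev_slope·severity − tilt_slope·REM tilt + noise))."""

    base: float = 29.5
    sev_slope: float = 3.0
    tilt_slope: float = 0.8
    noise_sd: float = 1.3


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a synthetic cohort.

    Defaults encode the study conditions the package analyses: 50
    subjects per group, 128 Hz sampling, 30-s scoring epochs, 300 s of
    EEG per behavioral state, 0.3-log10-unit planted AD − HC contrasts
    with MCI halfway, and macrostructure parameters matching the
    emulated clinical cohorts.
    """

    n_per_group: int = 50
    fs: float = 128.0
    epoch_len_s: float = 30.0
    wake_duration_s: float = 300.0
    sleep_duration_s: float = 300.0
    scheme: BandScheme = DEFAULT_BANDS

    base_log10: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_LOG10))
    regional_offsets: tuple[tuple[str, str, tuple[str, ...], float], ...] = (
        DEFAULT_REGIONAL_OFFSETS)
    effects: tuple[PlantedEffect, ...] = DEFAULT_EFFECTS

    # between-subject variance components (log10 units)
    severity_sd: float = 0.35      # within-group spread of the severity latent
    subject_sd: float = 0.18       # subject × state × band offset
    channel_sd: float = 0.08       # independent per-cell noise
    tilt_coeff: float = 0.15       # spectral-tilt loading (slow +, fast −)
    tilt_sd: float = 1.0           # SD of the tilt latents
    h_coupling: float = 0.15       # sleep fast-band loading of the h latent
    h_sd: float = 1.0
    tilt_rho: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TILT_RHO))

    # overnight waking-delta change model
    overnight_delta_drop: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OVERNIGHT_DROP))
    common_drop: float = DEFAULT_COMMON_DROP
    change_channels: tuple[str, ...] = REGIONS["frontal_central"]
    change_h_slope: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHANGE_H_SLOPE))
    change_noise_sd: float = 0.12

    mmse_coupling: MMSECoupling = MMSECoupling()

    # macrostructure
    sol_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SOL_PARAMS))
    n3_pct_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_N3_PCT_PARAMS))
    stage_pcts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_STAGE_PCTS.items()})
    tbt_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TBT_PARAMS))

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.fs <= 2 * self.scheme.max_hz:
            raise ValueError(
                f"fs ({self.fs}) must exceed twice the highest band edge "
                f"({self.scheme.max_hz})"
            )
        for name in ("severity_sd", "subject_sd", "channel_sd", "tilt_sd",
                     "h_sd", "change_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        names = set(self.scheme.names)
        for st in STATES:
            for b in names:
                if (st, b) not in self.base_log10:
                    raise ValueError(
                        f"base_log10 missing entry for state {st!r}, band {b!r}"
                    )
        for g in GROUPS:
            for m, sd in ((self.sol_params[g]), (self.tbt_params[g]),
                          (self.n3_pct_params[g])):
                if sd < 0:
                    raise ValueError(f"negative SD in macrostructure params for {g}")
        for eff in self.effects:
            unknown = set(eff.channels) - set(MONTAGE_1020)
            if unknown:
                raise ValueError(f"effect references unknown channels {sorted(unknown)}")

    # -- deterministic group-level targets ---------------------------------

    def target_log10(self, group: str, state: str, channel: str, band: str) -> float:
        """Group-mean log10 power for a cell (severity at its group mean)."""
        v = self.base_log10[(state, band)]
        for st, b, chans, off in self.regional_offsets:
            if st == state and b == band and channel in chans:
                v += off
        sev = GROUP_SEVERITY[group]
        for eff in self.effects:
            if eff.state == state and eff.band == band and channel in eff.channels:
                v += eff.amplitude * sev / 2.0
        if state == "AM_WAKE" and band == "delta":
            # morning delta = evening delta + overnight change
            v = self.target_log10(group, "PM_WAKE", channel, band)
            if channel in self.change_channels:
                v += self.overnight_delta_drop[group]
            else:
                v += self.common_drop
        return v

    def planted_channels(self, state: str, band: str) -> set[str]:
        """Channels carrying a planted group effect for a state × band map."""
        out: set[str] = set()
        for eff in self.effects:
            if eff.state == state and eff.band == band:
                out |= set(eff.channels)
        if state == "AM_WAKE":
            out |= self.planted_channels("PM_WAKE", band)
            if band == "delta":
                out |= set(self.change_channels)
        return out

    def zero_variance(self) -> "CohortSpec":
        """Copy with every stochastic component silenced (degenerate spec)."""
        return dataclasses.replace(
            self, severity_sd=0.0, subject_sd=0.0, channel_sd=0.0,
            tilt_coeff=0.0, tilt_sd=0.0, h_coupling=0.0, h_sd=0.0,
            change_noise_sd=0.0,
            change_h_slope={g: 0.0 for g in GROUPS},
            mmse_coupling=dataclasses.replace(self.mmse_coupling, noise_sd=0.0),
        )

    def null(self) -> "CohortSpec":
        """Copy with every group effect removed (global null for EEG maps).

        Latent couplings that differ only in correlation structure, not
        in group means or variances, are kept; planted mean contrasts,
        group-dependent overnight drops and AD-specific couplings go.
        """
        return dataclasses.replace(
            self, effects=(),
            overnight_delta_drop={g: self.common_drop for g in GROUPS},
            change_h_slope={g: 0.0 for g in GROUPS},
            tilt_rho={g: 0.5 for g in GROUPS},
        )

    def hypnogram_params(self, group: str) -> HypnogramParams:
        mean_sol, _ = self.sol_params[group]
        p_onset = min(1.0, (self.epoch_len_s / 60.0) / max(mean_sol, 1e-9))
        return HypnogramParams(p_onset=p_onset,
                               sleep_stage_probs=self.stage_pcts[group])


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    group: str
    mmse: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not 0 <= self.mmse <= 30:
            raise ValueError(f"mmse must be in [0, 30], got {self.mmse}")


@dataclass
class CohortDataset:
    """One generated cohort: subjects, hypnograms and EEG content.

    Exactly one of ``signals`` (signal mode) or ``band_powers``
    (table-only mode) is populated.
    """

    subjects: list[SubjectRecord]
    hypnograms: dict[str, Hypnogram]
    signals: dict[str, dict[str, MultichannelSignal]] | None
    band_powers: pd.DataFrame | None
    spec: CohortSpec
    seed: int

    def __post_init__(self) -> None:
        ids = {s.id for s in self.subjects}
        if set(self.hypnograms) != ids:
            raise ValueError("hypnograms must cover exactly the subject ids")

    def subjects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"id": s.id, "group": s.group, "mmse": s.mmse} for s in self.subjects]
        )

    def to_disk(self, out_dir: str | Path) -> None:
        """Write subjects.tsv, hypnograms/<id>.csv, bandpower.tsv, manifest.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects_frame().to_csv(out / "subjects.tsv", sep="\t", index=False)
        hdir = out / "hypnograms"
        hdir.mkdir(exist_ok=True)
        for sid, h in self.hypnograms.items():
            write_hypnogram_csv(h, hdir / f"{sid}.csv")
        if self.band_powers is not None:
            write_bandpower_tsv(self.band_powers, out / "bandpower.tsv")
        manifest = {
            "seed": self.seed,
            "mode": "table" if self.band_powers is not None else "signal",
            "n_per_group": self.spec.n_per_group,
            "fs": self.spec.fs,
            "bands": {b.name: [b.low_hz, b.high_hz] for b in self.spec.scheme},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# hypnogram generation

def generate_hypnogram(params: HypnogramParams, epoch_len_s: float,
                       tbt_min: float, seed: int | np.random.Generator) -> Hypnogram:
    """Simulate one staged night as a Markov chain over {W, N1, N2, N3, R}.

    The record starts at lights-off in wake. During the latency phase
    each epoch switches to sleep with probability ``p_onset`` (0 gives
    an all-wake night). After onset, sleep epochs awaken with
    probability ``p_awakening``, intra-sleep wake persists with
    probability ``p_wake_persist``, and sleep stages are drawn from the
    stationary ``sleep_stage_probs``.
    """
    if tbt_min <= 0:
        raise ValueError("tbt_min must be positive")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    n_epochs = max(1, int(round(tbt_min * 60.0 / epoch_len_s)))
    stage_names = list(params.sleep_stage_probs)
    stage_p = np.array([params.sleep_stage_probs[s] for s in stage_names])
    stage_p = stage_p / stage_p.sum()

    # run-length formulation of the chain: the latency phase ends after a
    # geometric(p_onset) number of W epochs; sleep and intra-sleep wake
    # then alternate with geometric run lengths, which is exactly the
    # epoch-by-epoch Markov process.
    if params.p_onset == 0.0:
        return Hypnogram(("W",) * n_epochs, epoch_len_s=epoch_len_s)
    runs: list[tuple[bool, int]] = [(False, int(rng.geometric(params.p_onset)))]
    total = runs[0][1]
    asleep = True
    while total < n_epochs:
        if asleep:
            ln = (n_epochs - total if params.p_awakening == 0.0
                  else int(rng.geometric(params.p_awakening)))
        else:
            ln = (n_epochs - total if params.p_wake_persist == 1.0
                  else int(rng.geometric(1.0 - params.p_wake_persist)))
        runs.append((asleep, ln))
        total += ln
        asleep = not asleep

    cum = np.cumsum(stage_p)
    stages: list[str] = []
    for is_sleep, ln in runs:
        ln = min(ln, n_epochs - len(stages))
        if ln <= 0:
            break
        if is_sleep:
            draws = np.searchsorted(cum, rng.random(ln), side="right")
            stages.extend(stage_names[d] for d in draws)
        else:
            stages.extend(["W"] * ln)
    return Hypnogram(tuple(stages), epoch_len_s=epoch_len_s)


# ---------------------------------------------------------------------------
# signal synthesis

def generate_state_signal(power_targets: Mapping[str, Mapping[str, float]],
                          fs: float, duration_s: float,
                          seed: int | np.random.Generator,
                          scheme: BandScheme = DEFAULT_BANDS,
                          channels: Sequence[str] = MONTAGE_1020
                          ) -> MultichannelSignal:
    """Stationary band-limited noise mixture with prescribed band powers.

    ``power_targets[channel][band]`` is the target absolute power in
    µV². Each band component is Gaussian noise band-passed in the
    frequency domain over [low, high) and rescaled so its variance
    equals the target exactly; components are independent, so total
    variance ≈ the sum of the targets.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    n = int(round(duration_s * fs))
    if n < 2:
        raise ValueError("duration too short")
    scheme.validate_against_fs(fs)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    out = np.zeros((len(channels), n))
    for i, ch in enumerate(channels):
        targets = power_targets[ch]
        for b in scheme:
            p = float(targets.get(b.name, 0.0))
            if p < 0:
                raise ValueError(
                    f"channel {ch}, band {b.name}: negative power target {p}"
                )
            if p == 0.0:
                continue
            white = rng.standard_normal(n)
            spec = np.fft.rfft(white)
            spec[(freqs < b.low_hz) | (freqs >= b.high_hz)] = 0.0
            comp = np.fft.irfft(spec, n=n)
            var = comp.var()
            if var > 0:
                comp *= math.sqrt(p / var)
            out[i] += comp
    return MultichannelSignal(fs=fs, channel_labels=tuple(channels), samples=out)


# ---------------------------------------------------------------------------
# cohort generation

def _base_vector(spec: CohortSpec, state: str, band: str) -> np.ndarray:
    """Baseline + regional offsets per channel (severity-independent)."""
    v = np.full(len(MONTAGE_1020), spec.base_log10[(state, band)])
    for st, b, chs, off in spec.regional_offsets:
        if st == state and b == band:
            idx = [i for i, c in enumerate(MONTAGE_1020) if c in chs]
            v[idx] += off
    return v


def _effect_vector(spec: CohortSpec, state: str, band: str) -> np.ndarray:
    """Per-channel planted amplitude (AD − HC contrast) for a state × band."""
    e = np.zeros(len(MONTAGE_1020))
    for eff in spec.effects:
        if eff.state == state and eff.band == band:
            idx = [i for i, c in enumerate(MONTAGE_1020) if c in eff.channels]
            e[idx] += eff.amplitude
    return e


def _draw_log10_table(spec: CohortSpec, subjects: list[SubjectRecord],
                      latents: dict[str, np.ndarray],
                      rng: np.random.Generator) -> pd.DataFrame:
    """Per-subject log10 band-power draws for all states × channels × bands."""
    bands = spec.scheme.names
    chans = MONTAGE_1020
    n_ch = len(chans)
    n = len(subjects)
    fast = set(FAST_BANDS)
    group_arr = np.array([s.group for s in subjects])
    change_idx = np.array([i for i, c in enumerate(chans)
                           if c in spec.change_channels], dtype=int)
    drop = np.array([spec.overnight_delta_drop[g] for g in group_arr])
    h_slope = np.array([spec.change_h_slope[g] for g in group_arr])

    blocks: dict[tuple[str, str], np.ndarray] = {}
    pm_delta: np.ndarray | None = None
    for state in STATES:
        sev = latents["severity" if state in SLEEP_STATES else "severity_wake"]
        tilt = {"REM": latents["tilt_rem"], "PM_WAKE": latents["tilt_wake"],
                "AM_WAKE": latents["tilt_wake"]}.get(state)
        for band in bands:
            if state == "AM_WAKE" and band == "delta":
                # AM delta = the subject's PM values + overnight change
                change = np.full((n, n_ch), spec.common_drop)
                change[:, change_idx] = (drop - h_slope * latents["h"])[:, None]
                change += rng.normal(0.0, spec.change_noise_sd, size=(n, n_ch))
                vals = pm_delta + change
            else:
                mean = (_base_vector(spec, state, band)[None, :]
                        + _effect_vector(spec, state, band)[None, :]
                        * sev[:, None] / 2.0)
                if tilt is not None:
                    sign = -1.0 if band in fast else 1.0
                    mean = mean + spec.tilt_coeff * sign * tilt[:, None]
                if state in SLEEP_STATES and band in fast:
                    mean = mean + spec.h_coupling * latents["h"][:, None]
                vals = (mean
                        + rng.normal(0.0, spec.subject_sd, size=(n, 1))
                        + rng.normal(0.0, spec.channel_sd, size=(n, n_ch)))
            if state == "PM_WAKE" and band == "delta":
                pm_delta = vals
            blocks[(state, band)] = vals

    ids = np.array([s.id for s in subjects])
    keys = list(blocks)
    log10 = np.concatenate([blocks[k].ravel() for k in keys])
    block_len = n * n_ch
    df = pd.DataFrame({
        "subject": np.tile(np.repeat(ids, n_ch), len(keys)),
        "group": np.tile(np.repeat(group_arr, n_ch), len(keys)),
        "state": np.repeat(np.array([k[0] for k in keys]), block_len),
        "channel": np.tile(np.asarray(chans), n * len(keys)),
        "band": np.repeat(np.array([k[1] for k in keys]), block_len),
        "power_uv2": 10.0 ** log10,
        "log10_power": log10,
    })
    return df


def _draw_latents(spec: CohortSpec, subjects: list[SubjectRecord],
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-subject latent variables, each as an array aligned with subjects."""
    n = len(subjects)
    mu = np.array([GROUP_SEVERITY[s.group] for s in subjects])
    rho = np.array([spec.tilt_rho[s.group] for s in subjects])
    orth = np.sqrt(np.clip(1.0 - rho ** 2, 0.0, None))
    z = rng.standard_normal(n)
    zw = rho * z + orth * rng.standard_normal(n)
    t_rem = spec.tilt_sd * rng.standard_normal(n)
    t_wake = rho * t_rem + orth * spec.tilt_sd * rng.standard_normal(n)
    return {
        "severity": mu + spec.severity_sd * z,
        "severity_wake": mu + spec.severity_sd * zw,
        "tilt_rem": t_rem,
        "tilt_wake": t_wake,
        "h": spec.h_sd * rng.standard_normal(n),
    }


def _draw_mmse(spec: CohortSpec, subjects: list[SubjectRecord],
               latents: dict[str, np.ndarray],
               rng: np.random.Generator) -> dict[str, int]:
    c = spec.mmse_coupling
    raw = (c.base - c.sev_slope * latents["severity"]
           - c.tilt_slope * latents["tilt_rem"]
           + rng.normal(0.0, c.noise_sd, size=len(subjects)))
    vals = np.clip(np.round(raw), 0, 30).astype(int)
    return {s.id: int(v) for s, v in zip(subjects, vals)}


def generate_cohort(spec: CohortSpec, seed: int, mode: str = "table"
                    ) -> CohortDataset:
    """Generate a full synthetic cohort.

    ``mode="table"`` emits the band-power table directly from the
    log-normal model (fast); ``mode="signal"`` additionally synthesizes
    multichannel EEG per state whose band powers realize the same
    draws, so the two modes agree in distribution after spectral
    estimation. Identical (spec, seed, mode) gives identical output.
    """
    if mode not in ("table", "signal"):
        raise ValueError(f"mode must be 'table' or 'signal', got {mode!r}")
    rng = np.random.default_rng(seed)

    provisional = [
        SubjectRecord(id=f"{g}{i:03d}", group=g, mmse=30)
        for g in GROUPS for i in range(spec.n_per_group)
    ]
    latents = _draw_latents(spec, provisional, rng)
    mmse = _draw_mmse(spec, provisional, latents, rng)
    subjects = [dataclasses.replace(s, mmse=mmse[s.id]) for s in provisional]

    hypnograms: dict[str, Hypnogram] = {}
    for s in subjects:
        m_sol, sd_sol = spec.sol_params[s.group]
        sol = _gamma_draw(rng, m_sol, sd_sol, lo=spec.epoch_len_s / 60.0)
        m_tbt, sd_tbt = spec.tbt_params[s.group]
        tbt = max(120.0, rng.normal(m_tbt, sd_tbt))
        probs = _subject_stage_probs(spec, s.group, rng)
        params = HypnogramParams(
            p_onset=min(1.0, (spec.epoch_len_s / 60.0) / sol),
            sleep_stage_probs=probs,
        )
        hypnograms[s.id] = generate_hypnogram(params, spec.epoch_len_s, tbt, rng)

    table = _draw_log10_table(spec, subjects, latents, rng)

    if mode == "table":
        return CohortDataset(subjects=subjects, hypnograms=hypnograms,
                             signals=None, band_powers=table, spec=spec, seed=seed)

    signals: dict[str, dict[str, MultichannelSignal]] = {}
    wide = table.pivot_table(index=["subject", "state", "channel"],
                             columns="band", values="power_uv2")
    for s in subjects:
        signals[s.id] = {}
        for state in STATES:
            dur = (spec.wake_duration_s if state in WAKE_STATES
                   else spec.sleep_duration_s)
            targets = {
                ch: wide.loc[(s.id, state, ch)].to_dict() for ch in MONTAGE_1020
            }
            signals[s.id][state] = generate_state_signal(
                targets, spec.fs, dur, rng, scheme=spec.scheme)
    return CohortDataset(subjects=subjects, hypnograms=hypnograms,
                         signals=signals, band_powers=None, spec=spec, seed=seed)


def _gamma_draw(rng: np.random.Generator, mean: float, sd: float,
                lo: float) -> float:
    if sd == 0:
        return max(lo, mean)
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return max(lo, float(rng.gamma(shape, scale)))


def _subject_stage_probs(spec: CohortSpec, group: str,
                         rng: np.random.Generator) -> dict[str, float]:
    """Group stage distribution with subject-level jitter on the N3 share."""
    base = dict(spec.stage_pcts[group])
    m, sd = spec.n3_pct_params[group]
    n3 = max(0.0, rng.normal(m, sd)) / 100.0
    n3 = min(n3, 0.9)
    others = {k: v for k, v in base.items() if k != "N3"}
    rest = sum(others.values())
    scale = (1.0 - n3) / rest if rest > 0 else 0.0
    probs = {k: v * scale for k, v in others.items()}
    probs["N3"] = n3
    return probs
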