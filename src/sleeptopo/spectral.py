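"""Power spectral density estimation and band powers.

Welch's method (Hann window, 4-s windows, 50% overlap by default) on
multichannel EEG, followed by trapezoidal band integration over the
half-open bands of a :class:`~sleeptopo.bands.BandScheme`. The output of
:func:`build_band_power_table` — one row per subject × state × channel ×
band with absolute power in µV² and its log10 — is the central table
that every downstream statistic consumes.

Artifact policy: fixed-length segments containing any sample above an
amplitude threshold (default 300 µV) and flat (zero-variance) segments
are excluded before estimation; the PSD is the window-count-weighted
average over the remaining clean runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import BandScheme, DEFAULT_BANDS
from .montage import MONTAGE_1020

logger = logging.getLogger(__name__)

STATES: tuple[str, ...] = ("PM_WAKE", "NREM", "REM", "AM_WAKE")


@dataclass
class MultichannelSignal:
    """Channels × time EEG segment in µV."""

    fs: float
    channel_labels: tuple[str, ...]
    samples: np.ndarray  # shape (n_channels, n_samples)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels × time) array")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class WelchParams:
    window_s: float = 4.0
    overlap_frac: float = 0.5
    artifact_uv: float = 300.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap_frac must be in [0, 1)")


@dataclass
class PSD:
    """One-sided Welch PSD: density in µV²/Hz per channel."""

    freqs: np.ndarray  # (n_freqs,)
    density: np.ndarray  # (n_channels, n_freqs)
    channel_labels: tuple[str, ...]
    fs: float


def _clean_runs(x: np.ndarray, fs: float, seg_s: float, artifact_uv: float) -> list[np.ndarray]:
    """Split a (channels × time) array into maximal artifact-free runs.

    A segment of ``seg_s`` seconds is bad if any channel exceeds
    ``artifact_uv`` in absolute value or any channel is flat within it.
    """
    seg_len = int(round(seg_s * fs))
    n_seg = x.shape[1] // seg_len
    if n_seg == 0:
        return []
    good = np.ones(n_seg, dtype=bool)
    for i in range(n_seg):
        seg = x[:, i * seg_len : (i + 1) * seg_len]
        if np.any(np.abs(seg) > artifact_uv) or np.any(seg.std(axis=1) == 0):
            good[i] = False
    runs: list[np.ndarray] = []
    start = None
    for i in range(n_seg):
        if good[i] and start is None:
            start = i
        elif not good[i] and start is not None:
            runs.append(x[:, start * seg_len : i * seg_len])
            start = None
    if start is not None:
        runs.append(x[:, start * seg_len : n_seg * seg_len])
    return runs


def welch_psd(sig: MultichannelSignal, window_s: float = 4.0,
              overlap_frac: float = 0.5, artifact_uv: float | None = 300.0) -> PSD:
    """Welch PSD (Hann window) per channel, with artifact-segment rejection.

    The returned density is one-sided in µV²/Hz; its integral over
    [0, fs/2] approximates the signal variance (Parseval). Frequency
    resolution is 1/window_s.
    """
    nperseg = int(round(window_s * sig.fs))
    if sig.n_samples < 2 * nperseg:
        raise ValueError(
            f"signal of {sig.n_samples} samples is shorter than two "
            f"{window_s}-s windows ({2 * nperseg} samples)"
        )
    noverlap = int(round(overlap_frac * nperseg))

    if np.allclose(sig.samples, 0.0):
        # all-zero input: zero density (std==0 would otherwise reject everything)
        freqs = np.fft.rfftfreq(nperseg, d=1.0 / sig.fs)
        return PSD(freqs, np.zeros((len(sig.channel_labels), len(freqs))),
                   sig.channel_labels, sig.fs)

    if artifact_uv is None:
        runs = [sig.samples]
    else:
        runs = [r for r in _clean_runs(sig.samples, sig.fs, window_s, artifact_uv)
                if r.shape[1] >= nperseg]
        if not runs:
            raise ValueError("no artifact-free run of at least one window length")
        n_rej = sig.n_samples - sum(r.shape[1] for r in runs)
        if n_rej:
            logger.info("artifact rejection dropped %.1f s of %.1f s",
                        n_rej / sig.fs, sig.duration_s)

    dens_sum = None
    w_total = 0
    freqs = None
    step = nperseg - noverlap
    for r in runs:
        f, d = sps.welch(r, fs=sig.fs, window="hann", nperseg=nperseg,
                         noverlap=noverlap, detrend="constant", axis=-1)
        n_win = 1 + (r.shape[1] - nperseg) // step
        freqs = f
        dens_sum = d * n_win if dens_sum is None else dens_sum + d * n_win
        w_total += n_win
    return PSD(freqs, dens_sum / w_total, sig.channel_labels, sig.fs)


def band_power(psd: PSD, band: tuple[float, float]) -> np.ndarray:
    """Trapezoidal integral of the density over [low, high), per channel (µV²).

    Additive over disjoint contiguous bands that share edge frequencies.
    """
    low, high = band
    if low >= high:
        raise ValueError(f"empty band [{low}, {high})")
    if low < 0 or high > psd.fs / 2:
        raise ValueError(f"band [{low}, {high}) outside [0, {psd.fs / 2})")
    mask = (psd.freqs >= low) & (psd.freqs <= high)
    if mask.sum() < 2:
        raise ValueError(
            f"band [{low}, {high}) narrower than the frequency resolution"
        )
    return np.trapezoid(psd.density[:, mask], psd.freqs[mask], axis=-1)


def band_power_frame(psd: PSD, scheme: BandScheme = DEFAULT_BANDS) -> pd.DataFrame:
    """Band powers for every channel × band of a scheme, as a tidy frame."""
    scheme.validate_against_fs(psd.fs)
    rows = []
    for b in scheme:
        p = band_power(psd, (b.low_hz, b.high_hz))
        for ch, v in zip(psd.channel_labels, p):
            rows.append({"channel": ch, "band": b.name, "power_uv2": v})
    return pd.DataFrame(rows)


BANDPOWER_COLUMNS = ("subject", "group", "state", "channel", "band",
                     "power_uv2", "log10_power")


def build_band_power_table(cohort, scheme: BandScheme = DEFAULT_BANDS,
                           welch: WelchParams = WelchParams()) -> pd.DataFrame:
    """Subject × state × channel × band power table for a cohort.

    Works for both cohort modes: in table-only mode the generator's
    band-power rows are passed through; in signal mode each per-state
    signal is run through :func:`welch_psd` + :func:`band_power`.
    Exactly one row per subject × available state × channel × band.
    """
    if cohort.band_powers is not None:
        df = cohort.band_powers.copy()
        _validate_table(df)
        return df

    groups = {s.id: s.group for s in cohort.subjects}
    frames = []
    for sid, by_state in cohort.signals.items():
        for state, sig in by_state.items():
            missing = [c for c in MONTAGE_1020 if c not in sig.channel_labels]
            if missing:
                raise ValueError(
                    f"subject {sid!r}, state {state}: missing channel(s) {missing}"
                )
            psd = welch_psd(sig, welch.window_s, welch.overlap_frac, welch.artifact_uv)
            bp = band_power_frame(psd, scheme)
            bp.insert(0, "subject", sid)
            bp.insert(1, "group", groups[sid])
            bp.insert(2, "state", state)
            frames.append(bp)
    df = pd.concat(frames, ignore_index=True)
    df["log10_power"] = np.log10(df["power_uv2"])
    _validate_table(df)
    return df


def _validate_table(df: pd.DataFrame) -> None:
    missing = set(BANDPOWER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"band-power table missing columns: {sorted(missing)}")
    if (df["power_uv2"] <= 0).any():
        bad = df.loc[df["power_uv2"] <= 0]
        raise ValueError(f"non-positive band power for {len(bad)} row(s)")
    dup = df.duplicated(["subject", "state", "channel", "band"])
    if dup.any():
        raise ValueError("duplicate subject × state × channel × band rows")


def read_bandpower_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _validate_table(df)
    return df


def write_bandpower_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_edf(path: str | Path, channels: tuple[str, ...] = MONTAGE_1020) -> MultichannelSignal:
    """Read a multichannel EEG segment from an EDF file (requires mne)."""
    import mne  # optional dependency; imported lazily

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    raw.pick(list(channels))
    data = raw.get_data(units="uV")
    return MultichannelSignal(fs=float(raw.info["sfreq"]),
                              channel_labels=tuple(raw.ch_names), samples=data)
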