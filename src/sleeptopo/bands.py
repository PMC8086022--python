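"""Frequency band schemes.

Bands are half-open intervals [low, high) in Hz, ordered and
non-overlapping. The default scheme is the standard clinical sleep-EEG
partition with the delta+theta range spanning the low-frequency
(0.5-7 Hz and slightly above) slowing range: delta [0.5, 5), theta
[5, 8), alpha [8, 12), sigma [12, 16), beta [16, 25).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Band:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(
                f"band {self.name!r}: low ({self.low_hz}) must be < high ({self.high_hz})"
            )
        if self.low_hz < 0:
            raise ValueError(f"band {self.name!r}: negative low edge")


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping set of named frequency bands."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band scheme must contain at least one band")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate band names in scheme: {names}")
        for prev, nxt in zip(self.bands, self.bands[1:]):
            if nxt.low_hz < prev.high_hz:
                raise ValueError(
                    f"bands {prev.name!r} and {nxt.name!r} overlap or are out of order"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    @property
    def max_hz(self) -> float:
        return self.bands[-1].high_hz

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def __getitem__(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    def edges(self, name: str) -> tuple[float, float]:
        b = self[name]
        return (b.low_hz, b.high_hz)

    def validate_against_fs(self, fs: float) -> None:
        if self.max_hz >= fs / 2:
            raise ValueError(
                f"highest band edge {self.max_hz} Hz must be below Nyquist ({fs / 2} Hz)"
            )


DEFAULT_BANDS = BandScheme(
    (
        Band("delta", 0.5, 5.0),
        Band("theta", 5.0, 8.0),
        Band("alpha", 8.0, 12.0),
        Band("sigma", 12.0, 16.0),
        Band("beta", 16.0, 25.0),
    )
)

#: bands entering the numerator (slow) and denominator (fast) of the slowing index
SLOW_BANDS: tuple[str, ...] = ("delta", "theta")
FAST_BANDS: tuple[str, ...] = ("alpha", "sigma", "beta")
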