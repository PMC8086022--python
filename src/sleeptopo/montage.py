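"""19-channel 10-20 scalp montage and named channel regions.

The montage is the classic clinical 10-20 set (old nomenclature: T3/T4
for T7/T8, T5/T6 for P7/P8). Region sets are used by the synthetic
cohort generator to place group effects and by tests to check where
significant channels land.
"""

from __future__ import annotations

MONTAGE_1020: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

REGIONS: dict[str, tuple[str, ...]] = {
    "prefrontal": ("Fp1", "Fp2"),
    "frontal": ("F7", "F3", "Fz", "F4", "F8"),
    "central": ("C3", "Cz", "C4"),
    "temporal": ("T3", "T4", "T5", "T6"),
    "parietal": ("P3", "Pz", "P4"),
    "occipital": ("O1", "O2"),
    # composite regions used when planting topographic effects
    "frontotemporal": ("Fp1", "Fp2", "F7", "F3", "F4", "F8", "T3", "T4"),
    "right_frontotemporal": ("Fp2", "F4", "F8", "T4"),
    "posterior": ("T5", "P3", "Pz", "P4", "T6", "O1", "O2"),
    "temporo_occipital": ("T5", "T6", "O1", "O2"),
    "frontal_central": ("F3", "Fz", "F4", "C3", "Cz", "C4", "P3"),
}


def validate_channels(channels, montage=MONTAGE_1020) -> None:
    """Raise ValueError if any channel label is not in the montage."""
    unknown = [c for c in channels if c not in montage]
    if unknown:
        raise ValueError(f"unknown channel label(s): {unknown!r}; montage is {list(montage)}")
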