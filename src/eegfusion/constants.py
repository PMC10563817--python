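"""Shared acquisition constants: montage, class coding, canonical EEG bands."""

from __future__ import annotations

# 19-electrode subset of the international 10-20 system, in montage order.
MONTAGE_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

# Diagnostic class coding: normal control 0, frontotemporal dementia 1,
# Alzheimer's disease 2.
CLASS_NAMES: tuple[str, ...] = ("NC", "FTD", "AD")
NC, FTD, AD = 0, 1, 2

# Canonical EEG rhythm bands (Hz), contiguous from 0.5 to 45.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 25.0),
    "gamma": (25.0, 45.0),
}
BAND_NAMES: tuple[str, ...] = tuple(BAND_EDGES)

DEFAULT_FS: float = 250.0
DEFAULT_DURATION_S: float = 40.0
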