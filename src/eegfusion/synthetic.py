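"""Seeded synthetic resting-state EEG cohorts with class-conditional spectra.

The generator emulates the qualitative electrophysiology of dementia cohorts:
relative to normal controls (NC), Alzheimer's disease (AD) recordings carry
elevated delta/theta power and depressed alpha power, with frontotemporal
dementia (FTD) intermediate.  Each recording is a sum over the five canonical
bands of band-limited Gaussian noise (white noise passed through a zero-phase
4th-order Butterworth band-pass), scaled by a per-class gain profile, plus
white sensor noise.  Every subject also receives a raw Mini-Mental State
Examination (MMSE) score drawn uniformly within its class band (the banding
used by :mod:`eegfusion.two_factor`).

All randomness flows through a single integer seed; identical arguments give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .constants import (
    AD,
    BAND_EDGES,
    BAND_NAMES,
    DEFAULT_DURATION_S,
    DEFAULT_FS,
    FTD,
    MONTAGE_19,
    NC,
)

__all__ = [
    "BandGainProfile",
    "EegRecording",
    "CohortConfig",
    "band_gain_profile",
    "generate_recording",
    "generate_cohort",
]


@dataclass(frozen=True)
class BandGainProfile:
    """Relative (dimensionless) power gain per canonical band."""

    gains: dict[str, float]

    def __post_init__(self):
        missing = set(BAND_NAMES) - set(self.gains)
        if missing:
            raise ValueError(f"profile missing bands: {sorted(missing)}")
        extra = set(self.gains) - set(BAND_NAMES)
        if extra:
            raise ValueError(f"unknown bands in profile: {sorted(extra)}")
        if any(g < 0 for g in self.gains.values()):
            raise ValueError("band gains must be non-negative")
        if all(g == 0 for g in self.gains.values()):
            raise ValueError("at least one band gain must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.gains[b] for b in BAND_NAMES])


@dataclass
class EegRecording:
    """One subject's multichannel EEG with its label and MMSE score."""

    data: np.ndarray  # channels x samples, microvolts
    fs: float
    channel_labels: tuple[str, ...] = MONTAGE_19
    class_label: int = NC
    mmse_raw: int | None = None
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data must be (n_channels={len(self.channel_labels)}, samples); "
                f"got {self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.mmse_raw is not None and not (0 <= self.mmse_raw <= 30):
            raise ValueError("MMSE raw score must lie in [0, 30]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# Class gain profiles, chosen once as a plausible qualitative contrast:
# NC alpha-dominant; AD slow-wave dominant with suppressed alpha; FTD in
# between element-wise for the delta/theta/alpha triplet.
_CLASS_PROFILES: dict[int, dict[str, float]] = {
    NC: {"delta": 0.6, "theta": 0.7, "alpha": 1.6, "beta": 0.8, "gamma": 0.4},
    FTD: {"delta": 1.0, "theta": 1.1, "alpha": 1.1, "beta": 0.7, "gamma": 0.35},
    AD: {"delta": 1.4, "theta": 1.5, "alpha": 0.6, "beta": 0.6, "gamma": 0.3},
}

# MMSE raw-score draw ranges per class (inclusive), matching the screening
# bands used downstream: AD >= 27, FTD 10-26, NC <= 9 under the as-printed
# banding (see eegfusion.two_factor for the banding and its caveat).
MMSE_RANGES: dict[int, tuple[int, int]] = {AD: (27, 30), FTD: (10, 26), NC: (0, 9)}


def band_gain_profile(class_label: int, contrast: float = 1.0) -> BandGainProfile:
    """Return the band-power gain profile for a diagnostic class.

    ``contrast`` in [0, 1] linearly interpolates between the class-neutral
    mean profile (0: all classes identical) and the full class profile (1).
    Pure function: same arguments always give the same profile.
    """
    if class_label not in _CLASS_PROFILES:
        raise ValueError(f"unknown class label {class_label!r}; expected 0, 1 or 2")
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    mean = {
        b: float(np.mean([p[b] for p in _CLASS_PROFILES.values()])) for b in BAND_NAMES
    }
    cls = _CLASS_PROFILES[class_label]
    gains = {b: mean[b] + contrast * (cls[b] - mean[b]) for b in BAND_NAMES}
    return BandGainProfile(gains)


def _band_limited_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                        fs: float, low: float, high: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass of white Gaussian noise, unit power."""
    white = rng.standard_normal((n_channels, n_samples))
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    band = signal.sosfiltfilt(sos, white, axis=1)
    # normalise to unit average power so the profile gain sets the band power
    rms = np.sqrt(np.mean(band**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return band / rms


def generate_recording(
    class_label: int,
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
    n_channels: int = len(MONTAGE_19),
    profile: BandGainProfile | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    mmse_raw: int | None = None,
    subject_id: str = "",
    mixing: np.ndarray | None = None,
) -> EegRecording:
    """Generate one synthetic recording with the given band-power profile.

    The signal is ``sum_b gain_b * bandlimited_noise_b + noise_sd * white``;
    channels are independent unless a cross-channel ``mixing`` matrix is
    given (default identity).
    """
    if duration_s < 40:
        raise ValueError("standard pipeline requires duration >= 40 s")
    if fs <= 2 * BAND_EDGES["gamma"][1]:
        raise ValueError(
            f"sampling rate {fs} Hz too low: need fs > {2 * BAND_EDGES['gamma'][1]} Hz "
            "(Nyquist above the gamma upper edge)"
        )
    if profile is None:
        profile = band_gain_profile(class_label)
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    data = np.zeros((n_channels, n_samples))
    for band in BAND_NAMES:
        gain = profile.gains[band]
        low, high = BAND_EDGES[band]
        noise = _band_limited_noise(rng, n_channels, n_samples, fs, low, high)
        if gain > 0:
            data += np.sqrt(gain) * noise
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal((n_channels, n_samples))
    if mixing is not None:
        mixing = np.asarray(mixing)
        if mixing.shape != (n_channels, n_channels):
            raise ValueError("mixing matrix must be (n_channels, n_channels)")
        data = mixing @ data
    labels = MONTAGE_19 if n_channels == len(MONTAGE_19) else tuple(
        f"ch{i:02d}" for i in range(n_channels)
    )
    return EegRecording(
        data=data,
        fs=fs,
        channel_labels=labels,
        class_label=class_label,
        mmse_raw=mmse_raw,
        subject_id=subject_id,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    ``class_counts`` of (29, 23, 36) reproduces the reference cohort sizes
    (NC, FTD, AD); the default draws ``n_per_class`` of each.
    """

    duration_s: float = DEFAULT_DURATION_S
    fs: float = DEFAULT_FS
    n_channels: int = len(MONTAGE_19)
    noise_sd: float = 0.1
    contrast: float = 1.0
    class_counts: tuple[int, int, int] | None = None  # (NC, FTD, AD)
    mmse_ranges: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(MMSE_RANGES)
    )


def generate_cohort(
    n_per_class: int = 5, seed: int = 0, config: CohortConfig | None = None
) -> list[EegRecording]:
    """Generate a labelled cohort, ``n_per_class`` subjects per class.

    MMSE raw scores are drawn uniformly within each class's screening band.
    Deterministic for fixed ``(n_per_class, seed, config)``.
    """
    if config is None:
        config = CohortConfig()
    counts = config.class_counts or (n_per_class,) * 3
    if any(c < 1 for c in counts):
        raise ValueError("need at least one subject per class")
    master = np.random.default_rng(seed)
    recordings: list[EegRecording] = []
    sub = 0
    for cls, count in zip((NC, FTD, AD), counts):
        profile = band_gain_profile(cls, contrast=config.contrast)
        lo, hi = config.mmse_ranges[cls]
        for _ in range(count):
            sub += 1
            rec_seed = int(master.integers(0, 2**31 - 1))
            mmse = int(master.integers(lo, hi + 1))
            recordings.append(
                generate_recording(
                    cls,
                    duration_s=config.duration_s,
                    fs=config.fs,
                    n_channels=config.n_channels,
                    profile=profile,
                    noise_sd=config.noise_sd,
                    seed=rec_seed,
                    mmse_raw=mmse,
                    subject_id=f"sub-{sub:03d}",
                )
            )
    return recordings
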