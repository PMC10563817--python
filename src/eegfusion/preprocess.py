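"""Recording -> model inputs: 4-s time segments and five band-filtered signals.

Two parallel representations feed the dual-branch network: non-overlapping
time-domain windows (transformer branch) and the five canonical band signals
obtained by zero-phase Butterworth band-pass filtering (CNN branch).  A Welch
power-spectral-density estimator is provided both as an analysis tool and as
the oracle used to validate the generator's spectral structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .constants import BAND_EDGES, BAND_NAMES
from .synthetic import EegRecording

__all__ = [
    "SegmentSet",
    "BandSet",
    "Psd",
    "segment_time_domain",
    "decompose_bands",
    "welch_psd",
    "band_power",
    "band_power_features",
    "normalize_recording",
]


@dataclass
class SegmentSet:
    """Non-overlapping, contiguous time windows from the start of a recording."""

    segments: list[np.ndarray]  # each channels x window_samples
    window_s: float
    subject_id: str = ""

    def __post_init__(self):
        shapes = {s.shape for s in self.segments}
        if len(shapes) > 1:
            raise ValueError(f"segments differ in shape: {shapes}")

    def as_array(self) -> np.ndarray:
        """(n_segments, channels, window_samples) stack."""
        return np.stack(self.segments)


@dataclass
class BandSet:
    """Band-filtered versions of a recording, one matrix per canonical band."""

    bands: dict[str, np.ndarray]
    band_edges: dict[str, tuple[float, float]]

    def __post_init__(self):
        if tuple(self.bands) != BAND_NAMES:
            raise ValueError(f"expected bands {BAND_NAMES}, got {tuple(self.bands)}")

    def as_array(self) -> np.ndarray:
        """(n_bands, channels, samples) stack in canonical band order."""
        return np.stack([self.bands[b] for b in BAND_NAMES])


@dataclass
class Psd:
    """Welch power spectral density per channel."""

    freqs: np.ndarray
    power: np.ndarray  # channels x len(freqs)

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("PSD power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def normalize_recording(rec: EegRecording) -> EegRecording:
    """Per-channel z-score of the whole recording.

    Applied before segmentation/decomposition so that the relative power
    split across bands — the class-discriminative structure — is preserved
    while absolute amplitude scale is removed.
    """
    mean = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return EegRecording(
        data=(rec.data - mean) / sd,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        class_label=rec.class_label,
        mmse_raw=rec.mmse_raw,
        subject_id=rec.subject_id,
    )


def segment_time_domain(
    rec: EegRecording, window_s: float = 4.0, n_segments: int = 10, offset_s: float = 0.0
) -> SegmentSet:
    """Cut ``n_segments`` contiguous non-overlapping windows from ``offset_s``.

    Raises a ``ValueError`` naming the required vs available duration when
    the recording is too short.
    """
    window_samples = int(round(window_s * rec.fs))
    start = int(round(offset_s * rec.fs))
    needed = start + n_segments * window_samples
    if needed > rec.n_samples:
        raise ValueError(
            f"recording too short: need {needed / rec.fs:.1f} s "
            f"({n_segments} x {window_s} s windows), have {rec.duration_s:.1f} s"
        )
    segments = [
        rec.data[:, start + i * window_samples: start + (i + 1) * window_samples].copy()
        for i in range(n_segments)
    ]
    return SegmentSet(segments=segments, window_s=window_s, subject_id=rec.subject_id)


def decompose_bands(rec: EegRecording, order: int = 4) -> BandSet:
    """Split a recording into the five canonical bands.

    Each band signal is produced by zero-phase (forward-backward) Butterworth
    band-pass filtering of every channel, so the decomposition is linear and
    introduces no group delay.
    """
    if rec.fs <= 2 * BAND_EDGES["gamma"][1]:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for the gamma band "
            f"(need > {2 * BAND_EDGES['gamma'][1]} Hz)"
        )
    bands: dict[str, np.ndarray] = {}
    for name in BAND_NAMES:
        low, high = BAND_EDGES[name]
        sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
        bands[name] = signal.sosfiltfilt(sos, rec.data, axis=1)
    return BandSet(bands=bands, band_edges=dict(BAND_EDGES))


def welch_psd(
    x: np.ndarray, fs: float, window_s: float = 2.0, overlap_frac: float = 0.5
) -> Psd:
    """Welch average-periodogram PSD of a (channels, samples) signal.

    Hann windows of ``window_s`` seconds with fractional overlap
    ``overlap_frac``; density scaling, so integrating over frequency
    recovers signal power (within windowing loss).
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    nperseg = int(round(window_s * fs))
    if nperseg > x.shape[1]:
        raise ValueError(
            f"Welch window ({nperseg} samples) longer than signal ({x.shape[1]})"
        )
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    freqs, power = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap_frac), axis=1, scaling="density",
    )
    return Psd(freqs=freqs, power=power)


def band_power(psd: Psd, low: float, high: float) -> np.ndarray:
    """Integrated PSD per channel over [low, high) Hz (trapezoid rule)."""
    mask = (psd.freqs >= low) & (psd.freqs <= high)
    if mask.sum() < 2:
        raise ValueError(f"band [{low}, {high}] Hz covers fewer than 2 grid points")
    return np.trapezoid(psd.power[:, mask], psd.freqs[mask], axis=1)


def band_power_features(rec: EegRecording, **welch_kwargs) -> np.ndarray:
    """Per-band total power (summed over channels), a 5-vector feature."""
    psd = welch_psd(rec.data, rec.fs, **welch_kwargs)
    return np.array(
        [band_power(psd, *BAND_EDGES[b]).sum() for b in BAND_NAMES]
    )
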