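"""Raw-signal conditioning: band-pass, notch, offset removal, windowing.

The processing chain mirrors standard myoelectric practice: a fourth-order
Butterworth band-pass (20-450 Hz) keeps the surface-EMG energy band, a
narrow notch removes mains interference, per-channel mean subtraction
removes the DC offset, and a 128 ms sliding window with 50 ms stride cuts
each trial into the segments from which features are computed.

Filtering is causal (forward-only) by default, matching online processing of
a live recording; zero-phase filtering is available via ``zero_phase=True``.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass plus mains notch parameters.

    ``notch_freq`` defaults to the 50 Hz European mains frequency; ``notch_q``
    is the notch quality factor (centre frequency over -3 dB bandwidth).
    """

    order: int = 4
    low_cutoff: float = 20.0
    high_cutoff: float = 450.0
    notch_freq: float = 50.0
    notch_q: float = 30.0
    sampling_rate: float = 2000.0

    def __post_init__(self) -> None:
        nyq = self.sampling_rate / 2.0
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        if not 0 < self.low_cutoff < self.high_cutoff < nyq:
            raise ValueError(
                f"need 0 < low ({self.low_cutoff}) < high ({self.high_cutoff}) "
                f"< Nyquist ({nyq})"
            )
        if not 0 < self.notch_freq < nyq:
            raise ValueError(f"notch_freq {self.notch_freq} outside (0, {nyq})")
        if self.notch_q <= 0:
            raise ValueError("notch_q must be positive")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in milliseconds."""

    length_ms: float = 128.0
    stride_ms: float = 50.0

    def samples(self, sampling_rate: float) -> tuple[int, int]:
        """Window and stride lengths in samples; both must be whole counts."""
        w = self.length_ms * sampling_rate / 1000.0
        s = self.stride_ms * sampling_rate / 1000.0
        if abs(w - round(w)) > 1e-9 or abs(s - round(s)) > 1e-9:
            raise ValueError(
                f"window {self.length_ms} ms / stride {self.stride_ms} ms do not "
                f"map to whole samples at {sampling_rate} Hz"
            )
        w, s = int(round(w)), int(round(s))
        if w < 2 or s < 1:
            raise ValueError(f"degenerate window geometry ({w} samples, stride {s})")
        return w, s


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x[None, :] if x.ndim == 1 else x


@lru_cache(maxsize=64)
def _bandpass_sos_cached(order: int, low: float, high: float, fs: float) -> np.ndarray:
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


@lru_cache(maxsize=64)
def _notch_ba_cached(freq: float, q: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    return sps.iirnotch(freq, q, fs=fs)


def bandpass_sos(spec: FilterSpec) -> np.ndarray:
    """Second-order-section coefficients of the band-pass in ``spec``."""
    return _bandpass_sos_cached(spec.order, spec.low_cutoff, spec.high_cutoff,
                                spec.sampling_rate)


def bandpass(x: np.ndarray, spec: FilterSpec, zero_phase: bool = False) -> np.ndarray:
    """Band-pass filter each channel of a channels x time array."""
    x2 = _as_2d(x)
    if x2.shape[1] <= 3 * spec.order:
        raise ValueError(
            f"signal of {x2.shape[1]} samples too short for order-{spec.order} filter"
        )
    sos = bandpass_sos(spec)
    out = sps.sosfiltfilt(sos, x2, axis=1) if zero_phase else sps.sosfilt(sos, x2, axis=1)
    return out.reshape(np.asarray(x).shape)


def notch(x: np.ndarray, spec: FilterSpec, zero_phase: bool = False) -> np.ndarray:
    """Remove mains interference with a narrow IIR notch."""
    x2 = _as_2d(x)
    if x2.shape[1] <= 3 * spec.order:
        raise ValueError(f"signal of {x2.shape[1]} samples too short to notch-filter")
    b, a = _notch_ba_cached(spec.notch_freq, spec.notch_q, spec.sampling_rate)
    out = sps.filtfilt(b, a, x2, axis=1) if zero_phase else sps.lfilter(b, a, x2, axis=1)
    return out.reshape(np.asarray(x).shape)


def remove_offset(x: np.ndarray) -> np.ndarray:
    """Subtract the per-channel mean (DC offset correction)."""
    x2 = _as_2d(x)
    out = x2 - x2.mean(axis=1, keepdims=True)
    return out.reshape(np.asarray(x).shape)


def window_count(n_samples: int, window: int, stride: int) -> int:
    """Number of full windows: floor((T - w) / s) + 1; the remainder is dropped."""
    if n_samples < window:
        raise ValueError(f"signal of {n_samples} samples shorter than one {window}-sample window")
    return (n_samples - window) // stride + 1


def windows(x: np.ndarray, wspec: WindowSpec, sampling_rate: float
            ) -> tuple[np.ndarray, np.ndarray]:
    """Cut channels x time into overlapping segments.

    Returns ``(segments, starts)`` where ``segments`` has shape
    (n_windows, channels, window_samples) and ``starts`` holds the sample
    index at which each window begins (0, stride, 2*stride, ...).
    """
    x2 = _as_2d(x)
    w, s = wspec.samples(sampling_rate)
    n = window_count(x2.shape[1], w, s)
    view = np.lib.stride_tricks.sliding_window_view(x2, w, axis=1)[:, ::s, :]
    segments = np.ascontiguousarray(view[:, :n, :].transpose(1, 0, 2))
    starts = np.arange(n) * s
    return segments, starts


def majority_label(labels: Sequence[int]) -> int:
    """Modal label of a window's samples; ties resolve to the smallest label."""
    if len(labels) == 0:
        raise ValueError("cannot take the majority of an empty label list")
    counts = Counter(labels)
    best = max(counts.values())
    return min(lab for lab, c in counts.items() if c == best)


def zscore_fit(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension mean and standard deviation from *training* features.

    Constant dimensions get sd 0 and a warning; :func:`zscore_apply` maps
    them to 0 so they carry no discriminative signal.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need a 2-D feature array with at least 2 training samples")
    mean = features.mean(axis=0)
    sd = features.std(axis=0)
    if np.any(sd == 0):
        warnings.warn(
            f"{int((sd == 0).sum())} constant feature dimension(s); z-score maps them to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return mean, sd


def zscore_apply(features: np.ndarray, stats: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Apply training z-score statistics to (train or held-out) features."""
    mean, sd = stats
    features = np.asarray(features, dtype=np.float64)
    safe = np.where(sd == 0, 1.0, sd)
    out = (features - mean) / safe
    return np.where(sd == 0, 0.0, out)
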