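"""Hudgins time-domain features.

The classic four-descriptor set for myoelectric control, computed per window
and channel:

* MAV — mean absolute value, (1/w) * sum |x_t|
* ZC  — zero crossings: sign changes between consecutive samples whose
  amplitude step exceeds a deadband
* SSC — slope sign changes: interior samples that are a local extremum,
  (x_t - x_{t-1}) * (x_t - x_{t+1}) > deadband
* WL  — waveform length, sum |x_{t+1} - x_t|

A 16-channel window therefore yields a 64-dimensional vector.  The layout is
channel-major — ``[ch0: MAV, ZC, SSC, WL, ch1: MAV, ...]`` — so that all
features of one sensor occupy a contiguous block.  Deadbands default to 0
because published pipelines rarely state them; they are exposed in
:class:`FeatureThresholds` for the classical small-threshold variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FEATURE_NAMES = ("mav", "zc", "ssc", "wl")


@dataclass(frozen=True)
class FeatureThresholds:
    """Amplitude (ZC) and slope (SSC) deadbands; both default to 0."""

    zc_eps: float = 0.0
    ssc_eps: float = 0.0

    def __post_init__(self) -> None:
        if self.zc_eps < 0 or self.ssc_eps < 0:
            raise ValueError("deadbands must be non-negative")


def mav(window: np.ndarray) -> float:
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValueError("empty window")
    return float(np.abs(window).mean())


def zero_crossings(window: np.ndarray, th: FeatureThresholds = FeatureThresholds()) -> int:
    window = np.asarray(window, dtype=np.float64)
    if window.size < 2:
        raise ValueError("zero crossings need at least 2 samples")
    a, b = window[:-1], window[1:]
    return int(np.count_nonzero((a * b < 0) & (np.abs(a - b) > th.zc_eps)))


def slope_sign_changes(window: np.ndarray, th: FeatureThresholds = FeatureThresholds()) -> int:
    window = np.asarray(window, dtype=np.float64)
    if window.size < 3:
        raise ValueError("slope sign changes need at least 3 samples")
    prev_d = window[1:-1] - window[:-2]
    next_d = window[1:-1] - window[2:]
    return int(np.count_nonzero(prev_d * next_d > th.ssc_eps))


def waveform_length(window: np.ndarray) -> float:
    window = np.asarray(window, dtype=np.float64)
    if window.size < 2:
        raise ValueError("waveform length needs at least 2 samples")
    return float(np.abs(np.diff(window)).sum())


def extract(window: np.ndarray, th: FeatureThresholds = FeatureThresholds()) -> np.ndarray:
    """Hudgins vector of one multi-channel window (channels x samples).

    Returns the channel-major concatenation; element ``4*c + k`` is feature
    ``FEATURE_NAMES[k]`` of channel ``c``.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2:
        raise ValueError(f"expected a channels x samples window, got {window.ndim}-D")
    out = np.empty(window.shape[0] * 4)
    for c, row in enumerate(window):
        out[4 * c + 0] = mav(row)
        out[4 * c + 1] = zero_crossings(row, th)
        out[4 * c + 2] = slope_sign_changes(row, th)
        out[4 * c + 3] = waveform_length(row)
    return out


def extract_batch(segments: np.ndarray,
                  th: FeatureThresholds = FeatureThresholds()) -> np.ndarray:
    """Vectorised :func:`extract` over a stack of windows.

    ``segments`` has shape (n_windows, channels, samples) — the output of
    :func:`emgshift.preprocess.windows` — and the result is
    (n_windows, channels*4) in the same channel-major layout.
    """
    segments = np.asarray(segments, dtype=np.float64)
    if segments.ndim != 3:
        raise ValueError("expected (n_windows, channels, samples)")
    n, c, w = segments.shape
    if w < 3:
        raise ValueError("windows must hold at least 3 samples")
    mav_v = np.abs(segments).mean(axis=2)
    diff = np.diff(segments, axis=2)
    wl_v = np.abs(diff).sum(axis=2)
    a, b = segments[:, :, :-1], segments[:, :, 1:]
    zc_v = ((a * b < 0) & (np.abs(a - b) > th.zc_eps)).sum(axis=2)
    prev_d = segments[:, :, 1:-1] - segments[:, :, :-2]
    next_d = segments[:, :, 1:-1] - segments[:, :, 2:]
    ssc_v = (prev_d * next_d > th.ssc_eps).sum(axis=2)
    out = np.empty((n, c * 4))
    out[:, 0::4] = mav_v
    out[:, 1::4] = zc_v
    out[:, 2::4] = ssc_v
    out[:, 3::4] = wl_v
    return out


def feature_columns(n_channels: int = 16) -> list[str]:
    """Column names matching the channel-major feature layout."""
    return [f"ch{c:02d}_{name}" for c in range(n_channels) for name in FEATURE_NAMES]
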