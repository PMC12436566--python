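"""Signal conditioning chain for 10-s ECG segments.

Three stages, applied in order: baseline-drift removal, 50 Hz mains
band-stop, 40 Hz low-pass.  All filters are zero-phase (forward-
backward) so R- and T-peak amplitudes and timings stay comparable to
the clean signal — the T:R ratio is the quantity everything downstream
depends on, and a phase-distorting chain would bias it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .holter_io import Segment


@dataclass(frozen=True)
class FilterConfig:
    """Tunable parameters of the conditioning chain.

    Baseline correction uses a two-stage median filter (a standard
    drift estimator: the short window flattens QRS complexes, the long
    window follows the slow wander) whose output is subtracted from the
    signal.  The band-stop is a second-order IIR notch run forward-
    backward; the low-pass a 4th-order Butterworth, also zero-phase.
    """

    median_window_1_s: float = 0.2
    median_window_2_s: float = 0.6
    notch_freq: float = 50.0
    notch_q: float = 30.0
    lowpass_cutoff: float = 40.0
    lowpass_order: int = 4


DEFAULT_FILTERS = FilterConfig()


def _as_array(segment) -> tuple[np.ndarray, float]:
    if isinstance(segment, Segment):
        return np.asarray(segment.samples, dtype=float), segment.sampling_rate
    raise TypeError("expected a Segment; use the *_array functions for raw arrays")


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def remove_baseline_array(x: np.ndarray, fs: float,
                          config: FilterConfig = DEFAULT_FILTERS) -> np.ndarray:
    """Subtract the two-stage median-filter drift estimate; re-center to zero mean."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < fs:
        raise ValueError("need at least 1 s of samples for baseline estimation")
    w1 = _odd(int(round(config.median_window_1_s * fs)))
    w2 = _odd(int(round(config.median_window_2_s * fs)))
    baseline = ndimage.median_filter(x, size=w1, mode="nearest")
    baseline = ndimage.median_filter(baseline, size=w2, mode="nearest")
    out = x - baseline
    return out - out.mean()


def notch_50hz_array(x: np.ndarray, fs: float,
                     config: FilterConfig = DEFAULT_FILTERS) -> np.ndarray:
    """Zero-phase band-stop at the mains frequency."""
    if fs <= 100.0:
        raise ValueError("sampling rate must exceed 100 Hz for a 50 Hz notch")
    b, a = signal.iirnotch(config.notch_freq, config.notch_q, fs=fs)
    return signal.filtfilt(b, a, np.asarray(x, dtype=float))


def lowpass_40hz_array(x: np.ndarray, fs: float,
                       config: FilterConfig = DEFAULT_FILTERS) -> np.ndarray:
    """Zero-phase Butterworth low-pass removing residual high-frequency noise."""
    if fs <= 2 * config.lowpass_cutoff:
        raise ValueError("sampling rate too low for the low-pass cutoff")
    sos = signal.butter(config.lowpass_order, config.lowpass_cutoff,
                        btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def preprocess_array(x: np.ndarray, fs: float,
                     config: FilterConfig = DEFAULT_FILTERS) -> np.ndarray:
    """Full chain: baseline removal, then band-stop, then low-pass."""
    x = remove_baseline_array(x, fs, config)
    x = notch_50hz_array(x, fs, config)
    return lowpass_40hz_array(x, fs, config)


def _wrap(segment: Segment, samples: np.ndarray) -> Segment:
    return replace(segment, samples=samples)


def remove_baseline(segment: Segment, config: FilterConfig = DEFAULT_FILTERS) -> Segment:
    x, fs = _as_array(segment)
    return _wrap(segment, remove_baseline_array(x, fs, config))


def notch_50hz(segment: Segment, config: FilterConfig = DEFAULT_FILTERS) -> Segment:
    x, fs = _as_array(segment)
    return _wrap(segment, notch_50hz_array(x, fs, config))


def lowpass_40hz(segment: Segment, config: FilterConfig = DEFAULT_FILTERS) -> Segment:
    x, fs = _as_array(segment)
    return _wrap(segment, lowpass_40hz_array(x, fs, config))


def preprocess_segment(segment: Segment, config: FilterConfig = DEFAULT_FILTERS) -> Segment:
    x, fs = _as_array(segment)
    return _wrap(segment, preprocess_array(x, fs, config))
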