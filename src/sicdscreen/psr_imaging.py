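"""Phase-space-reconstruction imaging of ECG segments.

A 10-s segment x[0..N-1] is embedded as the delay pairs
(x[t], x[t+tau]) and rasterized into a 32x32 occupancy histogram after
per-segment min-max amplitude normalization.  The resulting image is a
compact, amplitude-scale-invariant summary of the waveform geometry:
the QRS loop and the T-wave excursion occupy distinct regions whose
extent along the diagonal tracks the relative T amplitude — which is
what makes these images a usable input for T:R regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .holter_io import ECGRecording, Segment, segment_recording
from .preprocess import FilterConfig, DEFAULT_FILTERS, preprocess_segment

logger = logging.getLogger(__name__)

#: Delay in samples: 20 ms at 500 Hz, a small fraction of the QRS width.
DEFAULT_TAU = 10
DEFAULT_BINS = 32


@dataclass
class PSRImage:
    """32x32 delay-map occupancy image of one segment.

    ``intensity`` is the raw 2-D histogram divided by its maximum cell
    count, so values lie in [0, 1] with at least one pixel exactly 1.
    Row index = bin of x[t] (row 0 = lowest amplitude), column index =
    bin of x[t+tau].
    """

    intensity: np.ndarray
    tau: int
    channel_role: str = ""
    segment_index: int = -1

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (DEFAULT_BINS, DEFAULT_BINS):
            raise ValueError(
                f"PSR image must be {DEFAULT_BINS}x{DEFAULT_BINS}, "
                f"got {self.intensity.shape}"
            )
        if self.intensity.min() < 0 or self.intensity.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")


def psr_histogram(x: np.ndarray, tau: int, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Raw delay-pair occupancy counts (total mass = N - tau).

    Bins are equal-width on [0, 1] after min-max normalization; the
    final bin is right-closed so a value of exactly 1.0 lands in bin
    ``bins - 1``.  A constant segment has undefined normalization; by
    convention its single repeated pair is placed on the center
    diagonal pixel.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if tau < 1:
        raise ValueError("tau must be >= 1 sample")
    if n <= tau:
        raise ValueError("segment must be longer than tau")
    lo, hi = x.min(), x.max()
    counts = np.zeros((bins, bins))
    if hi == lo:
        logger.warning("constant segment: degenerate PSR image (single pixel)")
        counts[bins // 2, bins // 2] = n - tau
        return counts
    u = (x - lo) / (hi - lo)
    counts, _, _ = np.histogram2d(u[:-tau], u[tau:], bins=bins, range=[[0, 1], [0, 1]])
    return counts


def psr_image(segment: Segment | np.ndarray, tau: int = DEFAULT_TAU,
              bins: int = DEFAULT_BINS) -> PSRImage:
    """Build the max-normalized PSR image of one (preprocessed) segment."""
    if isinstance(segment, Segment):
        x = segment.samples
        role, idx = segment.channel_role, segment.segment_index
    else:
        x, role, idx = np.asarray(segment, dtype=float), "", -1
    counts = psr_histogram(x, tau, bins)
    return PSRImage(intensity=counts / counts.max(), tau=tau,
                    channel_role=role, segment_index=idx)


def batch_images(recording: ECGRecording, tau: int = DEFAULT_TAU,
                 window_s: float = 10.0, preprocess: bool = True,
                 filter_config: FilterConfig = DEFAULT_FILTERS
                 ) -> dict[str, list[PSRImage]]:
    """Segment, condition and image every present channel, order preserved."""
    segments = segment_recording(recording, window_s=window_s)
    out: dict[str, list[PSRImage]] = {}
    for role, segs in segments.items():
        images = []
        for seg in segs:
            if preprocess:
                seg = preprocess_segment(seg, filter_config)
            images.append(psr_image(seg, tau=tau))
        out[role] = images
    return out
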