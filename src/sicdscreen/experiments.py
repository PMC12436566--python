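"""Reproducible end-to-end experiments on synthetic cohorts.

These drive the full pipeline — generation, conditioning, imaging,
regression, screening — at desk scale with explicit seeds, and back
both the test suite and the results-reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import holter_io, preprocess, psr_imaging, synthetic_data, tr_estimation
from .psr_imaging import PSRImage
from .synthetic_data import TRTrajectory, default_config


def labeled_image_dataset(seed: int, n_recordings: int = 34,
                          segments_per_recording: int = 20,
                          tr_range: tuple[float, float] = (0.1, 0.9),
                          noise: synthetic_data.NoiseModel | None = None
                          ) -> tuple[list[PSRImage], np.ndarray, np.ndarray]:
    """Generate labeled PSR images from synthetic recordings.

    Each recording contributes ``segments_per_recording`` 10-s segments
    per channel, with per-segment T:R targets drawn uniformly from
    ``tr_range`` (so labels cover the whole screening-relevant band
    rather than one subject's narrow trajectory).  Default size:
    34 x 20 x 3 = 2040 labeled segments.  Returns ``(images, labels,
    groups)`` with ``groups`` the recording index of each image — the
    cross-validation fold unit.
    """
    rng = np.random.default_rng(seed)
    images: list[PSRImage] = []
    labels: list[float] = []
    groups: list[int] = []
    for i in range(n_recordings):
        cfg = default_config(
            duration_s=segments_per_recording * 10.0,
            seed=int(rng.integers(2**31)),
            noise=noise,
        )
        for ch in cfg.channels.values():
            ch.trajectory = TRTrajectory(
                per_segment_target=rng.uniform(*tr_range, segments_per_recording)
            )
        recording, truth = synthetic_data.generate_recording(cfg)
        segments = holter_io.segment_recording(recording)
        for role in recording.roles:
            for k, seg in enumerate(segments[role]):
                clean = preprocess.preprocess_segment(seg)
                images.append(psr_imaging.psr_image(clean))
                labels.append(truth[role][k])
                groups.append(i)
    return images, np.asarray(labels), np.asarray(groups)


def crossval_experiment(seed: int, n_recordings: int = 34,
                        segments_per_recording: int = 20,
                        n_folds: int = 10):
    """Tenfold recording-grouped CV of the PSR-image T:R regressor.

    Returns ``(model, AccuracyReport)`` with pooled out-of-fold MSE,
    RMSE and MAE against the generator's ground-truth ratios.
    """
    images, labels, groups = labeled_image_dataset(
        seed, n_recordings=n_recordings,
        segments_per_recording=segments_per_recording,
    )
    return tr_estimation.train_regressor(
        images, labels, n_folds=n_folds, seed=seed, groups=groups
    )


def screen_synthetic_cohort(n_per_subgroup: dict[str, int], base_seed: int,
                            duration_s: float = 1200.0):
    """Generate, estimate (oracle backend) and screen a synthetic cohort.

    Returns ``(patient_results, summary)`` as produced by
    ``screening.cohort_screen``.
    """
    from . import screening

    cohort = synthetic_data.generate_cohort(
        n_per_subgroup, base_seed=base_seed, duration_s=duration_s
    )
    cohort_series = []
    for recording, _truth in cohort:
        series = tr_estimation.tr_series(recording, backend="oracle")
        cohort_series.append((recording.subject_id, recording.subgroup, series))
    return screening.cohort_screen(cohort_series)
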