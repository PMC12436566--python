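"""Oracle estimator accuracy, metric algebra, and the CV harness."""

import numpy as np
import pytest

from sicdscreen import holter_io, preprocess, synthetic_data as sd
from sicdscreen.psr_imaging import PSRImage, psr_image
from sicdscreen.tr_estimation import (
    AccuracyReport,
    evaluate,
    oracle_tr,
    predict_tr,
    train_regressor,
    tr_series,
)


def _clean_segment(tr, seed=7):
    cfg = sd.default_config(duration_s=10.0, seed=seed, noise=sd.ZERO_NOISE)
    cfg.channels["primary"].trajectory = sd.TRTrajectory(
        per_segment_target=np.array([tr]) if tr > 0 else None
    )
    if tr == 0:
        cfg.channels["primary"].trajectory = sd.TRTrajectory(
            per_segment_target=np.array([1e-3])
        )
    rec, truth = sd.generate_recording(cfg)
    seg = holter_io.segment_recording(rec)["primary"][0]
    return preprocess.preprocess_segment(seg), truth["primary"][0]


class TestOracle:
    @pytest.mark.parametrize("tr", [0.2, 0.33, 0.6, 0.9])
    def test_recovers_known_ratio(self, tr):
        seg, truth = _clean_segment(tr)
        assert abs(oracle_tr(seg) - truth) < 0.02

    def test_near_zero_t_gives_near_zero_ratio(self):
        seg, _ = _clean_segment(0)
        assert oracle_tr(seg) < 0.05

    def test_beatless_segment_yields_missing(self):
        # a flat segment has no envelope peaks at all -> <3 beats -> NaN
        assert np.isnan(oracle_tr(np.zeros(5000), fs=500.0))
        seg = holter_io.Segment("primary", 0, np.zeros(5000), 500.0)
        assert np.isnan(oracle_tr(seg))

    def test_amplitude_scale_invariant(self):
        seg, _ = _clean_segment(0.4)
        a = oracle_tr(seg.samples, fs=500.0)
        b = oracle_tr(seg.samples * 13.7, fs=500.0)
        assert abs(a - b) < 1e-12


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = evaluate([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert rep.mse == rep.rmse == rep.mae == 0.0

    def test_constant_offset(self):
        rep = evaluate(np.array([0.3, 0.5]) + 0.1, [0.3, 0.5])
        assert abs(rep.mae - 0.1) < 1e-12 and abs(rep.rmse - 0.1) < 1e-12

    def test_hand_computed_example(self):
        rep = evaluate([0.2, 0.6], [0.3, 0.4])
        assert abs(rep.mae - 0.15) < 1e-12
        assert abs(rep.mse - 0.025) < 1e-12
        assert abs(rep.rmse - np.sqrt(0.025)) < 1e-12

    def test_metric_identities(self):
        rng = np.random.default_rng(2)
        p, y = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        rep = evaluate(p, y)
        assert abs(rep.rmse**2 - rep.mse) < 1e-9
        assert rep.mae <= rep.rmse + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])


@pytest.fixture(scope="module")
def tiny_dataset():
    """Structured images whose diagonal extent encodes the label."""
    rng = np.random.default_rng(10)
    images, labels, groups = [], [], []
    for i in range(120):
        tr = rng.uniform(0.1, 0.9)
        m = np.zeros((32, 32))
        k = 1 + int(tr * 30)
        m[:k, :k] = rng.uniform(0.2, 1.0, (k, k))
        m.flat[np.argmax(m)] = 1.0
        m[0, 0] = 1.0
        images.append(PSRImage(intensity=m, tau=10))
        labels.append(tr)
        groups.append(i // 12)
    return images, np.array(labels), np.array(groups)


class TestTrainRegressor:
    def test_learns_structured_mapping(self, tiny_dataset):
        images, labels, groups = tiny_dataset
        model, report = train_regressor(images, labels, n_folds=5,
                                        seed=0, groups=groups)
        assert report.mae < 0.1
        assert report.n == len(images)
        assert len(report.per_fold) == 5

    def test_deterministic_given_seed(self, tiny_dataset):
        images, labels, groups = tiny_dataset
        _, r1 = train_regressor(images, labels, n_folds=5, seed=3, groups=groups)
        _, r2 = train_regressor(images, labels, n_folds=5, seed=3, groups=groups)
        assert r1.mae == r2.mae and r1.per_fold == r2.per_fold

    def test_constant_labels_warns(self, tiny_dataset):
        images, _, groups = tiny_dataset
        with pytest.warns(UserWarning, match="constant labels"):
            train_regressor(images, np.full(len(images), 0.5), n_folds=5,
                            seed=0, groups=groups)

    def test_fewer_images_than_folds_rejected(self, tiny_dataset):
        images, labels, _ = tiny_dataset
        with pytest.raises(ValueError, match="n_folds"):
            train_regressor(images[:5], labels[:5], n_folds=10)

    def test_predict_contracts(self, tiny_dataset):
        images, labels, groups = tiny_dataset
        model, _ = train_regressor(images, labels, n_folds=5, seed=0, groups=groups)
        pred = predict_tr(model, images[0])
        assert np.isfinite(pred) and pred >= 0
        blank = PSRImage(intensity=np.zeros((32, 32)), tau=10)
        assert np.isfinite(predict_tr(model, blank))
        with pytest.raises(TypeError):
            predict_tr(model, np.zeros((32, 32)))


class TestTRSeries:
    def test_one_value_per_segment_per_channel(self, noisy_recording):
        recording, truth = noisy_recording
        series = tr_series(recording, backend="oracle")
        assert set(series) == {"primary", "alternate", "secondary"}
        for role, s in series.items():
            assert len(s) == 20 and not s.missing

    def test_oracle_tracks_ground_truth(self, noisy_recording):
        recording, truth = noisy_recording
        series = tr_series(recording, backend="oracle")
        for role in recording.roles:
            mask = np.isfinite(series[role].values)
            err = series[role].values[mask] - truth[role][mask]
            assert np.abs(err).mean() < 0.05

    def test_missing_channel_flagged(self):
        cfg = sd.default_config(duration_s=20.0, seed=2, noise=sd.ZERO_NOISE)
        del cfg.channels["secondary"]
        recording, _ = sd.generate_recording(cfg)
        series = tr_series(recording, backend="oracle")
        assert series["secondary"].missing
        assert not series["primary"].missing

    def test_model_backend_requires_model(self, noisy_recording):
        recording, _ = noisy_recording
        with pytest.raises(ValueError, match="model"):
            tr_series(recording, backend="model")


def test_parameter_recovery_over_cohort():
    """Oracle series over a noisy cohort: MAE <= 0.05, r >= 0.95 vs truth."""
    cohort = sd.generate_cohort({"Normal": 2, "HF": 2, "S-ICD": 1},
                                base_seed=21, duration_s=200.0)
    est_all, truth_all = [], []
    for recording, truth in cohort:
        series = tr_series(recording, backend="oracle")
        for role in recording.roles:
            mask = np.isfinite(series[role].values)
            est_all.append(series[role].values[mask])
            truth_all.append(truth[role][mask])
    est = np.concatenate(est_all)
    ref = np.concatenate(truth_all)
    assert np.abs(est - ref).mean() <= 0.05
    assert np.corrcoef(est, ref)[0, 1] >= 0.95
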