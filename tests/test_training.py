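"""Training-regime tests: the baseline/distilled equivalence at alpha=1,
loss-decomposition bookkeeping, teacher freezing, the alpha sweep, and
chained distillation."""

from dataclasses import replace

import numpy as np
import pytest

from fgl.bin_codec import fit_bins
from fgl.fgl_core import DistillConfig, fgl_loss, fgl_loss_parts
from fgl.mackey_glass import make_windows, split_train_test
from fgl.synthetic_events import generate_recording, label_segments
from fgl.training import (
    RunConfig,
    chain_distill,
    evaluate_regression,
    pretrain_teacher,
    sweep_alpha,
    train_student_baseline,
    train_student_fgl,
)

FAST = dict(epochs_teacher=5, epochs_student=5, hidden=(8,), bins=10, window_len=12)


@pytest.fixture(scope="module")
def small_regression(short_series):
    data = make_windows(short_series, 12, 5)
    train, test = split_train_test(data, 0.8)
    codec = fit_bins(train.y, 10)
    return train, test, codec


@pytest.fixture(scope="module")
def small_events():
    rec = generate_recording(
        n_channels=3, duration=900.0, fs=16.0, n_events=2, preictal_horizon=60.0,
        ictal_duration=20.0, seed=21,
    )
    return rec


class TestRegressionLoops:
    def test_alpha_one_reproduces_baseline_exactly(self, small_regression):
        train, _test, codec = small_regression
        cfg = RunConfig(horizon_n=5, seed=3, **FAST)
        teacher = pretrain_teacher(train, cfg, codec)
        base = train_student_baseline(train, cfg, codec)
        fgl1 = train_student_fgl(
            train, teacher, replace(cfg, distill=DistillConfig(alpha=1.0, tau=4.0)), codec
        )
        assert base.student.checksum() == fgl1.student.checksum()

    def test_deterministic_under_fixed_seed(self, small_regression):
        train, _test, codec = small_regression
        cfg = RunConfig(horizon_n=5, seed=9, **FAST)
        a = train_student_baseline(train, cfg, codec)
        b = train_student_baseline(train, cfg, codec)
        assert a.student.checksum() == b.student.checksum()
        t1 = pretrain_teacher(train, cfg, codec)
        t2 = pretrain_teacher(train, cfg, codec)
        assert t1.model.checksum() == t2.model.checksum()

    def test_teacher_frozen_through_student_training(self, small_regression):
        train, _test, codec = small_regression
        cfg = RunConfig(horizon_n=5, seed=3, **FAST)
        teacher = pretrain_teacher(train, cfg, codec)
        before = teacher.model.checksum()
        train_student_fgl(train, teacher, cfg, codec)
        assert teacher.model.checksum() == before
        assert teacher.model.verify()

    def test_loss_log_decomposition_consistent(self, small_regression):
        train, _test, codec = small_regression
        cfg = RunConfig(horizon_n=5, seed=3, **FAST)
        teacher = pretrain_teacher(train, cfg, codec)
        pair = train_student_fgl(train, teacher, cfg, codec)
        a, tau = cfg.distill.alpha, cfg.distill.tau
        for row in pair.student_log:
            assert row["total"] == pytest.approx(
                a * row["task"] + (1 - a) * tau**2 * row["kl"], rel=1e-9
            )
        # dual route: the decomposed parts re-assemble into fgl_loss
        logits = pair.student.forward(train.student_X[:16])
        t_logits = pair.teacher.forward(train.teacher_X[:16])
        targets = codec.encode(train.y[:16])
        task, _, kl, _, _ = fgl_loss_parts(logits, t_logits, targets, cfg.distill)
        assembled = a * task.mean() + (1 - a) * tau**2 * kl.mean()
        direct = fgl_loss(logits, t_logits, targets, cfg.distill)
        assert assembled == pytest.approx(direct, rel=1e-9)

    def test_baseline_loss_decreases_on_learnable_task(self, small_regression):
        train, _test, codec = small_regression
        cfg = RunConfig(horizon_n=5, seed=3, **dict(FAST, epochs_student=15))
        pair = train_student_baseline(train, cfg, codec)
        assert pair.student_log[-1]["task"] < pair.student_log[0]["task"]

    def test_unfrozen_teacher_rejected(self, small_regression):
        train, _test, codec = small_regression
        cfg = RunConfig(horizon_n=5, seed=3, **FAST)
        from fgl.models import ModelSpec, build_model

        raw = build_model(ModelSpec((1, 12), 10, seed=0))
        with pytest.raises(ValueError, match="frozen"):
            train_student_fgl(train, raw, cfg, codec)


class TestSweep:
    def test_alpha_one_row_matches_baseline_metric(self, small_regression):
        train, test, codec = small_regression
        cfg = RunConfig(horizon_n=5, seed=3, **FAST)
        teacher = pretrain_teacher(train, cfg, codec)
        table = sweep_alpha(train, teacher, cfg, [1.0, 0.5], codec=codec, eval_data=test)
        base = train_student_baseline(train, cfg, codec)
        expect = evaluate_regression(base.student, codec, test)["mse_bins"]
        row = table[table["alpha"] == 1.0].iloc[0]
        assert row["metric"] == pytest.approx(expect)
        assert len(table) == 2
        manual_best = table.loc[table["metric"].idxmin(), "alpha"]
        assert table.attrs["best_alpha"] == manual_best

    def test_empty_alphas_rejected(self, small_regression):
        train, _test, codec = small_regression
        cfg = RunConfig(horizon_n=5, seed=3, **FAST)
        with pytest.raises(ValueError):
            sweep_alpha(train, None, cfg, [], codec=codec)


class TestChain:
    def test_single_horizon_plain_model(self, short_series):
        cfg = RunConfig(horizon_n=1, seed=3, **FAST)
        out = chain_distill(short_series, [1], cfg)
        assert len(out["models"]) == 1
        assert out["link_mean_kl"] == []

    def test_two_level_chain_links_and_kl(self, short_series):
        cfg = RunConfig(horizon_n=1, seed=3, **FAST)
        out = chain_distill(short_series, [1, 3], cfg)
        assert len(out["models"]) == 2
        assert len(out["link_mean_kl"]) == 1
        assert np.isfinite(out["link_mean_kl"][0])

    def test_three_level_kl_per_link(self, short_series):
        cfg = RunConfig(horizon_n=1, seed=3, **FAST)
        out = chain_distill(short_series, [1, 3, 6], cfg)
        assert len(out["link_mean_kl"]) == 2
        assert all(np.isfinite(k) for k in out["link_mean_kl"])

    def test_non_ascending_rejected(self, short_series):
        cfg = RunConfig(horizon_n=1, seed=3, **FAST)
        with pytest.raises(ValueError, match="ascending"):
            chain_distill(short_series, [3, 1], cfg)


class TestEventMode:
    def test_detection_teacher_sees_no_preictal(self, small_events):
        detect = label_segments(small_events, 32, 32, task="detection")
        assert np.all(np.isin(detect.labels, [0, 1]))
        assert detect.n_excluded_preictal > 0
        cfg = RunConfig(
            mode="event", horizon_n=1, seed=5, epochs_teacher=3, epochs_student=3,
            hidden=(8,), frontend="bandpower", teacher_view="aligned",
        )
        teacher = pretrain_teacher(detect, cfg)
        assert teacher.preictal_excluded == detect.n_excluded_preictal

    def test_prediction_dataset_rejected_for_teacher(self, small_events):
        predict = label_segments(small_events, 32, 32, task="prediction")
        cfg = RunConfig(mode="event", epochs_teacher=2, epochs_student=2, hidden=(8,))
        with pytest.raises(ValueError, match="detection"):
            pretrain_teacher(predict, cfg)

    def test_event_student_trains_against_detector(self, small_events):
        detect = label_segments(small_events, 32, 32, task="detection")
        predict = label_segments(small_events, 32, 32, task="prediction")
        cfg = RunConfig(
            mode="event", seed=5, epochs_teacher=5, epochs_student=5,
            hidden=(8,), frontend="bandpower", teacher_view="aligned", optimizer="adam",
        )
        teacher = pretrain_teacher(detect, cfg)
        pair = train_student_fgl(predict, teacher, cfg)
        logits = pair.student.forward(predict.windows[:4])
        assert logits.shape == (4, 2)
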