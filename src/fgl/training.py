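"""Training regimes: teacher pretraining, baseline student, future-guided student.

Three loops share one engine so that the baseline is the exact alpha=1
degenerate case of the future-guided objective (same initialization, same
batch order, same optimizer state evolution).  The teacher is always frozen
before any student sees it, and its logits over the full training set are
computed once up front — it never updates, so per-batch re-inference would
only cost time.

Regression mode: the teacher is a next-step forecaster.  For a student
window ending at x_t with target x_{t+n}, the teacher receives the window
ending at x_{t+n-1}, i.e. it predicts the same target from one step away
(``teacher_view="offset"``).  Event mode: a detector teacher (ictal vs
interictal) supervises a predictor student (preictal vs interictal) on the
same windows (``teacher_view="aligned"``), with a class map tying the
teacher's event class to the student's positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bin_codec import BinCodec, fit_bins
from .fgl_core import DistillConfig, fgl_loss_parts, softmax_t
from .mackey_glass import TimeSeries, WindowDataset, make_windows, split_train_test
from .models import FrozenModel, MLPModel, ModelSpec, build_model, freeze, make_optimizer

__all__ = [
    "RunConfig",
    "TrainedPair",
    "pretrain_teacher",
    "train_student_baseline",
    "train_student_fgl",
    "sweep_alpha",
    "chain_distill",
    "evaluate_regression",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one training run."""

    mode: str = "regression"  # "regression" | "event"
    horizon_n: int = 5
    offset_k: int = 0
    distill: DistillConfig = field(default_factory=DistillConfig)
    optimizer: str = "adam"
    lr: float = 1e-3
    epochs_teacher: int = 100
    epochs_student: int = 30
    batch_size: int = 64
    seed: int = 0
    bins: int = 25
    window_len: int = 24
    hidden: tuple[int, ...] = (64,)
    teacher_view: str = "offset"  # "offset" | "aligned"
    frontend: str = "raw"  # "raw" | "logpower" (event models use a power front-end)

    def __post_init__(self) -> None:
        if self.mode not in ("regression", "event"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.horizon_n < 1:
            raise ValueError("horizon_n must be >= 1")
        if self.epochs_teacher <= 0 or self.epochs_student <= 0:
            raise ValueError("epochs must be positive")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.teacher_view not in ("offset", "aligned"):
            raise ValueError(f"unknown teacher_view {self.teacher_view!r}")

    @classmethod
    def event_default(cls, **kw) -> "RunConfig":
        """Event-forecasting defaults: SGD 5e-4, tau 4, 50/25 epochs, aligned view."""
        base = dict(
            mode="event",
            optimizer="sgd",
            lr=5e-4,
            epochs_teacher=50,
            epochs_student=25,
            distill=DistillConfig(alpha=0.5, tau=4.0),
            teacher_view="aligned",
            hidden=(32,),
            frontend="bandpower",
        )
        base.update(kw)
        return cls(**base)


@dataclass
class TrainedPair:
    """A frozen teacher, its trained student, and the run bookkeeping."""

    teacher: FrozenModel | None
    student: MLPModel
    config: RunConfig
    teacher_log: list = field(default_factory=list)
    student_log: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# generic minibatch engine


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _fit_classifier(
    model: MLPModel,
    X: np.ndarray,
    targets: np.ndarray,
    config: RunConfig,
    epochs: int,
    rng: np.random.Generator,
    teacher_logits: np.ndarray | None = None,
    alpha: float | None = None,
) -> list[dict]:
    """Train ``model`` on (X, targets) under the future-guided objective.

    ``teacher_logits=None`` (or alpha=1) is the plain task loss.  Returns a
    per-epoch log with the decomposed task and KL terms; the logged total is
    always alpha * task + (1 - alpha) * tau^2 * kl.
    """
    cfg = config.distill
    if alpha is not None:
        cfg = replace(cfg, alpha=alpha)
    if teacher_logits is None:
        cfg = replace(cfg, alpha=1.0)
    opt = make_optimizer(config.optimizer, model, config.lr)
    log: list[dict] = []
    n = X.shape[0]
    for epoch in range(epochs):
        task_sum = kl_sum = 0.0
        for idx in _iter_batches(n, config.batch_size, rng):
            logits, cache = model.forward(X[idx], return_cache=True)
            t_logits = None if teacher_logits is None else teacher_logits[idx]
            task_loss, task_grad, kl, p_s, p_t = fgl_loss_parts(
                logits, t_logits, targets[idx], cfg
            )
            grad = cfg.alpha * task_grad
            if cfg.alpha < 1.0:
                grad = grad + (1.0 - cfg.alpha) * cfg.tau * (p_s - p_t)
            grad /= idx.size
            grads_W, grads_b = model.backward(cache, grad)
            opt.step(grads_W, grads_b)
            task_sum += task_loss.sum()
            kl_sum += kl.sum()
        task_mean = task_sum / n
        kl_mean = kl_sum / n
        log.append(
            {
                "epoch": epoch,
                "task": task_mean,
                "kl": kl_mean,
                "total": cfg.alpha * task_mean
                + (1.0 - cfg.alpha) * cfg.tau**2 * kl_mean,
            }
        )
    return log


# ---------------------------------------------------------------------------
# teacher


def _regression_teacher_sets(data: WindowDataset, codec: BinCodec):
    """Teacher training pairs: its own (next-step) windows and the shared targets."""
    return data.teacher_X, codec.encode(data.y)


def pretrain_teacher(data, config: RunConfig, codec: BinCodec | None = None) -> "TrainedTeacher":
    """Pretrain and freeze the teacher on its short-horizon task.

    Regression mode: ``data`` is a :class:`WindowDataset`; the teacher is
    trained on its own next-step windows against the shared binned targets
    (``codec`` required).  Event mode: ``data`` is a detection
    :class:`~fgl.synthetic_events.SegmentDataset` — ictal vs interictal
    windows with every preictal window excluded upstream (the exclusion
    count is carried on the dataset and re-reported here; a detector trained
    on preictal data would be too certain near events, destroying exactly
    the uncertainty the student needs distilled).
    """
    if config.mode == "regression":
        if codec is None:
            raise ValueError("regression teacher needs the shared BinCodec")
        X, targets = _regression_teacher_sets(data, codec)
        n_classes = codec.num_bins
        n_channels, wlen = 1, data.window_len
        excluded = 0
    else:
        if getattr(data, "task", None) != "detection":
            raise ValueError("event-mode teacher must be trained on a detection dataset")
        if int(np.sum(data.labels == 1)) == 0:
            raise ValueError("event-mode teacher training data contains no ictal windows")
        X, targets = data.windows, data.labels.astype(int)
        n_classes = 2
        n_channels, wlen = X.shape[1], X.shape[2]
        excluded = getattr(data, "n_excluded_preictal", 0)

    spec = ModelSpec(
        input_shape=(n_channels, wlen),
        num_classes=n_classes,
        hidden=config.hidden,
        seed=config.seed + 10_000,
        frontend=config.frontend,
    )
    model = build_model(spec)
    model.set_input_stats(X)
    rng = np.random.default_rng([config.seed, 1])
    log = _fit_classifier(model, X, targets, config, config.epochs_teacher, rng)
    frozen = freeze(
        model,
        provenance={
            "role": "teacher",
            "epochs": config.epochs_teacher,
            "seed": config.seed,
            "n_train": int(X.shape[0]),
            "preictal_excluded": int(excluded),
        },
    )
    return TrainedTeacher(model=frozen, log=log, preictal_excluded=int(excluded))


@dataclass
class TrainedTeacher:
    model: FrozenModel
    log: list
    preictal_excluded: int = 0


# ---------------------------------------------------------------------------
# students


def _student_sets(data, config: RunConfig, codec: BinCodec | None):
    if config.mode == "regression":
        X = data.student_X
        targets = codec.encode(data.y)
        teacher_X = data.teacher_X if config.teacher_view == "offset" else data.student_X
        n_classes = codec.num_bins
        shape = (1, data.window_len)
    else:
        if getattr(data, "task", None) != "prediction":
            raise ValueError("event-mode student must be trained on a prediction dataset")
        X = data.windows
        targets = data.labels.astype(int)
        teacher_X = X  # aligned view: detector scores the student's windows
        n_classes = 2
        shape = (X.shape[1], X.shape[2])
    return X, targets, teacher_X, n_classes, shape


def _build_student(config: RunConfig, n_classes: int, shape) -> MLPModel:
    spec = ModelSpec(
        input_shape=shape,
        num_classes=n_classes,
        hidden=config.hidden,
        seed=config.seed,
        frontend=config.frontend,
    )
    return build_model(spec)


def train_student_fgl(
    data, teacher: FrozenModel | TrainedTeacher, config: RunConfig, codec: BinCodec | None = None
) -> TrainedPair:
    """Train a student under the future-guided objective against a frozen teacher."""
    if isinstance(teacher, TrainedTeacher):
        teacher = teacher.model
    if not isinstance(teacher, FrozenModel):
        raise ValueError("teacher must be frozen before student training")
    X, targets, teacher_X, n_classes, shape = _student_sets(data, config, codec)
    t_raw_dim = int(np.prod(teacher.spec.input_shape))
    view_dim = int(np.prod(np.asarray(teacher_X.shape[1:])))
    if view_dim != t_raw_dim:
        raise ValueError(
            f"teacher expects {t_raw_dim} raw input features but the teacher view has "
            f"{view_dim}"
        )
    checksum_before = teacher.checksum()
    teacher_logits = teacher.forward(teacher_X)  # frozen: one inference pass
    student = _build_student(config, n_classes, shape)
    student.set_input_stats(X)
    rng = np.random.default_rng([config.seed, 2])
    log = _fit_classifier(
        student, X, targets, config, config.epochs_student, rng,
        teacher_logits=teacher_logits,
    )
    assert teacher.checksum() == checksum_before
    return TrainedPair(teacher=teacher, student=student, config=config, student_log=log)


def train_student_baseline(data, config: RunConfig, codec: BinCodec | None = None) -> TrainedPair:
    """Train the same student architecture on the task loss alone (no teacher)."""
    X, targets, _teacher_X, n_classes, shape = _student_sets(data, config, codec)
    student = _build_student(config, n_classes, shape)
    student.set_input_stats(X)
    rng = np.random.default_rng([config.seed, 2])
    log = _fit_classifier(student, X, targets, config, config.epochs_student, rng)
    return TrainedPair(teacher=None, student=student, config=config, student_log=log)


# ---------------------------------------------------------------------------
# evaluation helper (regression)


def evaluate_regression(
    model, codec: BinCodec, test_data: WindowDataset, decode: str = "argmax"
) -> dict:
    """Test-set error of a binned regression forecaster.

    Returns both the bin-index MSE (predicted bin index vs true bin index —
    the scale on which benchmark results are reported) and the value-space
    MSE of the decoded scalar prediction.
    """
    logits = model.forward(test_data.student_X)
    probs = softmax_t(logits, 1.0)
    true_idx = np.asarray(codec.encode(test_data.y))
    if decode == "argmax":
        pred_idx = np.argmax(probs, axis=-1)
        pred_val = codec.centers[pred_idx]
    elif decode == "expect":
        pred_val = probs @ codec.centers
        pred_idx = (pred_val - codec.lo) / codec.width - 0.5
    else:
        raise ValueError(f"unknown decode rule {decode!r}")
    return {
        "mse_bins": float(np.mean((pred_idx - true_idx) ** 2)),
        "mse_value": float(np.mean((pred_val - test_data.y) ** 2)),
        "n_test": int(len(test_data)),
    }


# ---------------------------------------------------------------------------
# alpha sweep


def sweep_alpha(
    data,
    teacher,
    config: RunConfig,
    alphas: Sequence[float],
    codec: BinCodec | None = None,
    eval_data=None,
    metric=None,
) -> pd.DataFrame:
    """One student run per alpha (shared seed), returning a (alpha, metric) table.

    The metric defaults to bin-index test MSE in regression mode (lower is
    better) and AUC-ROC in event mode (higher is better); ``best_alpha`` is
    stored in ``DataFrame.attrs``.
    """
    alphas = list(alphas)
    if not alphas:
        raise ValueError("alpha list must be non-empty")
    if any(not 0.0 <= a <= 1.0 for a in alphas):
        raise ValueError("alphas must lie in [0, 1]")
    rows = []
    for a in alphas:
        cfg_a = replace(config, distill=replace(config.distill, alpha=a))
        if a == 1.0:
            pair = train_student_baseline(data, cfg_a, codec=codec)
        else:
            pair = train_student_fgl(data, teacher, cfg_a, codec=codec)
        if metric is not None:
            m = metric(pair.student)
        elif config.mode == "regression":
            m = evaluate_regression(pair.student, codec, eval_data or data)["mse_bins"]
        else:
            from .evaluation import auc_roc

            ev = eval_data or data
            scores = softmax_t(pair.student.forward(ev.windows), 1.0)[:, 1]
            m = auc_roc(scores, ev.labels)
        rows.append({"alpha": a, "metric": m})
    table = pd.DataFrame(rows)
    higher_better = config.mode == "event" and metric is None
    best = table.loc[table["metric"].idxmax() if higher_better else table["metric"].idxmin()]
    table.attrs["best_alpha"] = float(best["alpha"])
    table.attrs["seed_policy"] = f"shared seed {config.seed} across alphas"
    return table


# ---------------------------------------------------------------------------
# hierarchical chained distillation


def chain_distill(
    series: TimeSeries,
    horizons: Sequence[int],
    config: RunConfig,
    train_fraction: float = 0.8,
) -> dict:
    """Chain future-guided distillation through intermediate horizons.

    Model 0 (shortest horizon) is trained plainly; model i+1 is trained with
    the future-guided objective using frozen model i as its teacher, the
    teacher's window offset so both predict the same target.  Every model
    acts as student to its predecessor and teacher to its successor,
    propagating uncertainty down the horizon hierarchy.  Returns the models,
    the shared codec, and per-link mean-KL diagnostics (the prediction-error
    analogue of a predictive-coding hierarchy).
    """
    horizons = [int(h) for h in horizons]
    if any(b <= a for a, b in zip(horizons, horizons[1:])):
        raise ValueError("horizons must be strictly ascending")
    if horizons[0] < 1:
        raise ValueError("horizons must be >= 1")

    # shared codec over the training region so every level exchanges
    # distributions in the same bin space
    n_train_raw = int(train_fraction * len(series))
    codec = fit_bins(series.values[:n_train_raw], config.bins)

    models: list[FrozenModel | MLPModel] = []
    link_kl: list[float] = []
    prev_model: FrozenModel | None = None
    prev_h: int | None = None
    for level, h in enumerate(horizons):
        cfg_h = replace(config, horizon_n=h)
        if prev_model is None:
            data = make_windows(series, config.window_len, h, teacher_horizon=1)
            train, _test = split_train_test(data, train_fraction)
            pair = train_student_baseline(train, cfg_h, codec=codec)
        else:
            data = make_windows(series, config.window_len, h, teacher_horizon=prev_h)
            train, _test = split_train_test(data, train_fraction)
            pair = train_student_fgl(train, prev_model, cfg_h, codec=codec)
            link_kl.append(float(pair.student_log[-1]["kl"]))
        prev_model = freeze(pair.student, provenance={"horizon": h, "level": level})
        prev_h = h
        models.append(prev_model)
    return {"models": models, "codec": codec, "horizons": horizons, "link_mean_kl": link_kl}
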