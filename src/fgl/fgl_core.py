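"""Future-guided distillation objective.

A frozen teacher operating in the relative future of the student (a shorter
forecasting horizon, or direct event detection) transfers its
lower-uncertainty predictive distribution to the student through a
temperature-scaled KL term.  The student minimizes

    L = alpha * L_task(S(x_t), y)  +  (1 - alpha) * tau^2 * KL(p_T^tau || p_S^tau)

where p^tau = softmax(logits / tau).  The tau^2 factor keeps the gradient
magnitude of the soft term roughly independent of the temperature, so alpha
retains its meaning across temperatures.  The KL direction is
teacher-first (mode-covering): the student is pulled to cover every bin the
teacher assigns mass to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DistillConfig", "softmax_t", "kl_divergence", "fgl_loss", "fgl_loss_grad"]


@dataclass(frozen=True)
class DistillConfig:
    """Hyperparameters of the future-guided objective.

    alpha : weight on the task term, in [0, 1].  alpha=1 is the plain task
        loss; alpha=0 trains on the distilled teacher signal alone.
    tau : distillation temperature, > 0.  Larger tau flattens both
        distributions, exposing the teacher's uncertainty structure.
    class_map : optional sequence mapping teacher class index -> student
        class index (injective), used when the teacher's label space differs
        from the student's (e.g. a detector teacher supervising a predictor
        student).  None means identical label spaces.
    task_kind : "cross-entropy" (default; one-hot target) or
        "mean-squared-error" (target interpreted as a real value compared to
        the softmax expectation over class indices).
    epsilon : optional probability floor applied inside the KL term; 0 (off)
        by default so that a true support mismatch is reported as infinite.
    """

    alpha: float = 0.5
    tau: float = 4.0
    class_map: tuple[int, ...] | None = None
    task_kind: str = "cross-entropy"
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.task_kind not in ("cross-entropy", "mean-squared-error"):
            raise ValueError(f"unknown task_kind: {self.task_kind!r}")
        if self.class_map is not None:
            cm = tuple(int(i) for i in self.class_map)
            if len(set(cm)) != len(cm):
                raise ValueError("class_map must be injective")
            object.__setattr__(self, "class_map", cm)
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


def softmax_t(logits, tau: float = 1.0) -> np.ndarray:
    """Temperature-scaled softmax along the last axis, max-stabilized."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    z = np.asarray(logits, dtype=float) / tau
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def kl_divergence(p_teacher, p_student) -> float | np.ndarray:
    """KL(p_teacher || p_student) in nats, with 0*ln(0/q) = 0.

    Returns ``inf`` where the student assigns zero mass to a class the
    teacher supports (no silent smoothing; configure
    ``DistillConfig.epsilon`` for a floor).
    """
    p = np.asarray(p_teacher, dtype=float)
    q = np.asarray(p_student, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    support = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(support, p * (np.log(np.where(support, p, 1.0)) - np.log(q)), 0.0)
    out = terms.sum(axis=-1)
    return float(out) if p.ndim == 1 else out


def _map_teacher_probs(p_teacher: np.ndarray, class_map, C_student: int) -> np.ndarray:
    """Relocate teacher probability mass into the student's class space."""
    p = np.atleast_2d(p_teacher)
    if class_map is None:
        if p.shape[-1] != C_student:
            raise ValueError(
                f"teacher has {p.shape[-1]} classes but student has {C_student}; "
                "provide a class_map"
            )
        return p_teacher
    cm = np.asarray(class_map, dtype=int)
    if cm.size != p.shape[-1]:
        raise ValueError("class_map length must equal teacher class count")
    if np.any(cm < 0) or np.any(cm >= C_student):
        raise ValueError("class_map entries must index student classes")
    out = np.zeros(p.shape[:-1] + (C_student,))
    out[..., cm] = p
    return out if np.asarray(p_teacher).ndim > 1 else out[0]


def _task_loss_and_grad(
    student_logits: np.ndarray, target, task_kind: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample task loss and its gradient w.r.t. the student logits."""
    z = np.atleast_2d(student_logits)
    C = z.shape[-1]
    p = softmax_t(z, 1.0)
    if task_kind == "cross-entropy":
        t = np.asarray(target)
        N = z.shape[0]
        # class indices if the target has one entry per sample (integer dtype
        # disambiguates the N == C corner); otherwise a one-hot/soft matrix
        as_indices = t.ndim == 0 or (
            t.ndim == 1 and t.size == N and (N != C or np.issubdtype(t.dtype, np.integer))
        )
        if as_indices:
            onehot = np.zeros_like(z)
            onehot[np.arange(N), np.atleast_1d(t).astype(int)] = 1.0
        else:
            onehot = np.atleast_2d(np.asarray(t, dtype=float))
        logp = np.log(p)
        loss = -(onehot * logp).sum(axis=-1)
        grad = p - onehot
    else:  # mean-squared-error on the softmax expectation over class indices
        t = np.atleast_1d(np.asarray(target, dtype=float))
        idx = np.arange(C, dtype=float)
        pred = p @ idx
        loss = (pred - t) ** 2
        # d pred / d z_j = p_j * (j - pred)
        grad = (2.0 * (pred - t))[:, None] * p * (idx[None, :] - pred[:, None])
    return loss, grad


def fgl_loss(student_logits, teacher_logits, target, cfg: DistillConfig) -> float:
    """Scalar future-guided loss for one sample or the mean over a batch.

    The teacher logits are treated as constants (the teacher is frozen);
    gradients flow only through the student logits.
    """
    loss, _ = fgl_loss_grad(student_logits, teacher_logits, target, cfg)
    return loss


def fgl_loss_grad(
    student_logits, teacher_logits, target, cfg: DistillConfig
) -> tuple[float, np.ndarray]:
    """Loss and analytic gradient w.r.t. the student logits.

    Returns ``(loss, grad)`` where ``loss`` is the batch mean and ``grad``
    has the shape of ``student_logits``.  The gradient of the KL term w.r.t.
    the student logits z is tau^2 * (1/tau) * (p_S^tau - p_T^tau)
    = tau * (p_S^tau - p_T^tau).
    """
    z_s = np.asarray(student_logits, dtype=float)
    single = z_s.ndim == 1
    z_s2 = np.atleast_2d(z_s)
    N, C = z_s2.shape
    parts = fgl_loss_parts(z_s, teacher_logits, target, cfg)
    task_loss, task_grad, kl, p_s_tau, p_t_tau = parts
    grad = cfg.alpha * task_grad
    if cfg.alpha < 1.0:
        grad = grad + (1.0 - cfg.alpha) * cfg.tau * (p_s_tau - p_t_tau)
    loss = cfg.alpha * task_loss.mean() + (1.0 - cfg.alpha) * cfg.tau**2 * np.mean(kl)
    grad = grad / N
    return float(loss), (grad[0] if single else grad)


def fgl_loss_parts(student_logits, teacher_logits, target, cfg: DistillConfig):
    """Decomposed pieces of the objective (used for logging and gradients).

    Returns ``(task_loss, task_grad, kl, p_student_tau, p_teacher_tau)`` with
    per-sample task losses and KL values.
    """
    z_s = np.atleast_2d(np.asarray(student_logits, dtype=float))
    C = z_s.shape[-1]
    task_loss, task_grad = _task_loss_and_grad(z_s, target, cfg.task_kind)
    if cfg.alpha == 1.0 and teacher_logits is None:
        zero = np.zeros(z_s.shape[0])
        return task_loss, task_grad, zero, softmax_t(z_s, cfg.tau), softmax_t(z_s, cfg.tau)
    z_t = np.atleast_2d(np.asarray(teacher_logits, dtype=float))
    p_t = softmax_t(z_t, cfg.tau)
    p_t = np.atleast_2d(_map_teacher_probs(p_t, cfg.class_map, C))
    p_s = softmax_t(z_s, cfg.tau)
    if cfg.epsilon > 0:
        p_t = np.clip(p_t, cfg.epsilon, None)
        p_t = p_t / p_t.sum(axis=-1, keepdims=True)
        p_s = np.clip(p_s, cfg.epsilon, None)
        p_s = p_s / p_s.sum(axis=-1, keepdims=True)
    kl = np.atleast_1d(kl_divergence(p_t, p_s))
    return task_loss, task_grad, kl, p_s, p_t
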