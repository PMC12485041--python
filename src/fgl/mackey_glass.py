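"""Mackey-Glass delay-differential benchmark generator and window slicing.

The Mackey-Glass system

    dx/dt = beta * x(t - tau_d) / (1 + x(t - tau_d)**n) - gamma * x(t)

is a scalar delay differential equation originally proposed as a model of
blood-cell production; at the standard parameters (beta=0.2, gamma=0.1,
n=10, tau_d=17) it is chaotic and is a canonical forecasting benchmark.
This module integrates the equation with a fixed-step RK4 scheme (delayed
values looked up from the stored trajectory with linear interpolation) and
slices the resulting trajectory into aligned teacher/student supervised
windows for horizon-n forecasting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MGParams",
    "TimeSeries",
    "WindowedSample",
    "WindowDataset",
    "integrate_mg",
    "make_windows",
    "split_train_test",
    "write_series_csv",
    "read_series_csv",
]


class MGDivergenceError(RuntimeError):
    """Raised when the integration produces a non-finite value."""


@dataclass(frozen=True)
class MGParams:
    """Parameters of the Mackey-Glass delay differential equation.

    Attributes
    ----------
    beta : float
        Production coefficient (dimensionless), > 0 (0 allowed for the
        degenerate pure-decay system).
    gamma : float
        Decay coefficient (dimensionless), > 0.
    exponent_n : float
        Nonlinearity exponent, >= 1.
    delay_tau : float
        Feedback delay in time units, > 0 and >= dt.
    dt : float
        Integration step in time units.
    x0 : float
        Constant initial history value, > 0.
    washout : int
        Number of initial steps discarded before the trajectory is returned.
    """

    beta: float = 0.2
    gamma: float = 0.1
    exponent_n: float = 10.0
    delay_tau: float = 17.0
    dt: float = 1.0
    x0: float = 1.2
    washout: int = 500

    def __post_init__(self) -> None:
        if self.beta < 0 or self.gamma <= 0:
            raise ValueError("beta must be >= 0 and gamma > 0")
        if self.exponent_n < 1:
            raise ValueError("exponent_n must be >= 1")
        if self.delay_tau <= 0 or self.dt <= 0:
            raise ValueError("delay_tau and dt must be positive")
        if self.delay_tau < self.dt:
            raise ValueError(
                f"delay ({self.delay_tau}) shorter than integration step ({self.dt})"
            )
        if self.x0 <= 0:
            raise ValueError("x0 must be positive")
        if self.washout < 0:
            raise ValueError("washout must be non-negative")


@dataclass(frozen=True)
class TimeSeries:
    """A scalar trajectory with its generation provenance."""

    values: np.ndarray
    dt: float
    params: MGParams
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must all be finite")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class WindowedSample:
    """One supervised forecasting sample with aligned teacher/student views.

    The student input window ends at index t and the target is x[t + n]
    (n = ``horizon_n``).  The teacher, a next-step forecaster, receives the
    window ending at index t + n - 1 so that it predicts the same target one
    step ahead of its own input.
    """

    student_input: np.ndarray
    teacher_input: np.ndarray
    target_value: float
    target_index: int
    horizon_n: int


class WindowDataset:
    """Maximal ordered collection of :class:`WindowedSample` as dense arrays.

    ``student_X[i]`` ends at series index ``student_end[i]``; ``teacher_X[i]``
    ends at ``student_end[i] + horizon_n - teacher_horizon``; ``y[i]`` is the
    series value at ``student_end[i] + horizon_n``.
    """

    def __init__(
        self,
        student_X: np.ndarray,
        teacher_X: np.ndarray,
        y: np.ndarray,
        student_end: np.ndarray,
        horizon_n: int,
        teacher_horizon: int = 1,
    ) -> None:
        self.student_X = student_X
        self.teacher_X = teacher_X
        self.y = y
        self.student_end = student_end
        self.horizon_n = int(horizon_n)
        self.teacher_horizon = int(teacher_horizon)

    @property
    def window_len(self) -> int:
        return int(self.student_X.shape[1])

    def __len__(self) -> int:
        return int(self.y.size)

    def __getitem__(self, i: int) -> WindowedSample:
        return WindowedSample(
            student_input=self.student_X[i],
            teacher_input=self.teacher_X[i],
            target_value=float(self.y[i]),
            target_index=int(self.student_end[i]) + self.horizon_n,
            horizon_n=self.horizon_n,
        )

    def subset(self, idx: np.ndarray | slice) -> "WindowDataset":
        return WindowDataset(
            self.student_X[idx],
            self.teacher_X[idx],
            self.y[idx],
            self.student_end[idx],
            self.horizon_n,
            self.teacher_horizon,
        )


def _mg_rhs(x: float, x_delayed: float, p: MGParams) -> float:
    return p.beta * x_delayed / (1.0 + x_delayed**p.exponent_n) - p.gamma * x


def integrate_mg(params: MGParams, length: int, seed: int = 0) -> TimeSeries:
    """Integrate the Mackey-Glass equation and return ``length`` samples.

    Fixed-step RK4; the delayed term is looked up from the stored trajectory
    with linear interpolation, so ``delay_tau / dt`` need not be an integer.
    The history on [-tau_d, 0] is the constant ``params.x0``.  The first
    ``params.washout`` integrated steps are discarded.  Deterministic for a
    fixed ``(params, length, seed)``; the seed is reserved for optional
    history jitter and unused by default.

    Raises
    ------
    MGDivergenceError
        If a non-finite value appears during integration (reports the step).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    p = params
    n_hist = int(np.ceil(p.delay_tau / p.dt)) + 1
    n_total = p.washout + length
    # xs[i] holds x at time (i - n_hist + 1) * dt; history is constant x0.
    xs = np.empty(n_hist + n_total, dtype=float)
    xs[:n_hist] = p.x0

    def delayed(time_idx: float) -> float:
        # value of x at continuous grid position time_idx (units of dt)
        pos = time_idx + (n_hist - 1)
        lo = int(np.floor(pos))
        frac = pos - lo
        if frac == 0.0:
            return xs[lo]
        return (1.0 - frac) * xs[lo] + frac * xs[lo + 1]

    d_steps = p.delay_tau / p.dt
    for i in range(n_total):
        # current time index i (grid units); advancing to i+1
        x = xs[n_hist - 1 + i]
        xd0 = delayed(i - d_steps)
        k1 = _mg_rhs(x, xd0, p)
        xdh = delayed(i + 0.5 - d_steps)
        k2 = _mg_rhs(x + 0.5 * p.dt * k1, xdh, p)
        k3 = _mg_rhs(x + 0.5 * p.dt * k2, xdh, p)
        xd1 = delayed(i + 1.0 - d_steps)
        k4 = _mg_rhs(x + p.dt * k3, xd1, p)
        nxt = x + p.dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.isfinite(nxt):
            raise MGDivergenceError(
                f"integration diverged (non-finite value) at step {i}"
            )
        xs[n_hist + i] = nxt

    values = xs[n_hist + p.washout :].copy()
    return TimeSeries(values=values, dt=p.dt, params=p, seed=seed)


def make_windows(
    series: TimeSeries | np.ndarray,
    window_len: int,
    horizon_n: int,
    teacher_horizon: int = 1,
) -> WindowDataset:
    """Slice a trajectory into the maximal set of aligned forecast windows.

    For each student window ending at index t (inclusive), the target is
    x[t + horizon_n] and the teacher window ends at
    t + horizon_n - teacher_horizon, so a ``teacher_horizon``-step teacher
    predicts the same target.  Windows are returned in temporal order and
    their count is ``len(series) - window_len - horizon_n + 1``.
    """
    values = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    L, n, m = int(window_len), int(horizon_n), int(teacher_horizon)
    if n < 1:
        raise ValueError("horizon_n must be >= 1")
    if not 1 <= m <= n:
        raise ValueError("teacher_horizon must be in [1, horizon_n]")
    if L < 1:
        raise ValueError("window_len must be >= 1")
    N = values.size
    count = N - L - n + 1
    if count < 1:
        raise ValueError(
            f"series of length {N} too short for window_len={L}, horizon_n={n}; "
            f"need at least {L + n} samples"
        )
    sw = np.lib.stride_tricks.sliding_window_view(values, L)
    ends = np.arange(L - 1, L - 1 + count)  # student window end indices
    student_X = sw[ends - L + 1].copy()
    teacher_ends = ends + n - m
    teacher_X = sw[teacher_ends - L + 1].copy()
    y = values[ends + n].copy()
    return WindowDataset(student_X, teacher_X, y, ends, n, m)


def split_train_test(
    samples: WindowDataset,
    train_fraction: float,
    purge_gap: int = 0,
) -> tuple[WindowDataset, WindowDataset]:
    """Chronological train/test split of a window dataset.

    The first ``floor(train_fraction * N)`` windows form the training set and
    the remainder the test set, so every test window lies strictly later in
    time.  With ``purge_gap > 0`` the last ``purge_gap`` training windows are
    dropped so that no training input overlaps the first test input
    (``purge_gap = window_len + horizon_n`` guarantees
    max train student end index < min test student start index).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if purge_gap < 0:
        raise ValueError("purge_gap must be >= 0")
    N = len(samples)
    n_train = int(np.floor(train_fraction * N))
    if n_train - purge_gap < 1 or N - n_train < 1:
        raise ValueError(
            f"split leaves an empty side: N={N}, n_train={n_train}, purge_gap={purge_gap}"
        )
    train = samples.subset(slice(0, n_train - purge_gap))
    test = samples.subset(slice(n_train, N))
    return train, test


def write_series_csv(path, series: TimeSeries) -> None:
    """Write a (time, value) CSV with generation parameters in `#` comments."""
    p = series.params
    header = (
        f"# mackey-glass beta={p.beta} gamma={p.gamma} n={p.exponent_n} "
        f"tau={p.delay_tau} dt={p.dt} x0={p.x0} washout={p.washout} seed={series.seed}\n"
        "time,value\n"
    )
    t = np.arange(len(series)) * series.dt
    body = "\n".join(f"{ti:.6f},{vi:.12g}" for ti, vi in zip(t, series.values))
    with open(path, "w") as fh:
        fh.write(header + body + "\n")


def read_series_csv(path) -> TimeSeries:
    """Read a series written by :func:`write_series_csv` (provenance restored)."""
    kw: dict[str, float] = {}
    seed = 0
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    data_lines = []
    for ln in lines:
        if ln.startswith("#"):
            for tok in ln[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    if k == "seed":
                        seed = int(v)
                    elif k in {"beta", "gamma", "n", "tau", "dt", "x0", "washout"}:
                        kw[k] = float(v)
        elif ln and not ln.startswith("time"):
            data_lines.append(ln)
    arr = np.loadtxt(io.StringIO("\n".join(data_lines)), delimiter=",")
    arr = np.atleast_2d(arr)
    params = MGParams(
        beta=kw.get("beta", 0.2),
        gamma=kw.get("gamma", 0.1),
        exponent_n=kw.get("n", 10.0),
        delay_tau=kw.get("tau", 17.0),
        dt=kw.get("dt", 1.0),
        x0=kw.get("x0", 1.2),
        washout=int(kw.get("washout", 500)),
    )
    return TimeSeries(values=arr[:, 1], dt=params.dt, params=params, seed=seed)
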