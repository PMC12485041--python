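"""Recast scalar regression as C-way classification over equal-width bins.

A :class:`BinCodec` partitions the observed value range into ``B`` equal-width
intervals.  Continuous targets are encoded as the index (or one-hot vector) of
the containing bin; predicted categorical distributions are decoded back to a
scalar either as the center of the argmax bin or as the expectation over bin
centers.  Exchanging same-dimensional categorical distributions is what lets a
short-horizon teacher supervise a long-horizon student through a KL term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["BinCodec", "fit_bins"]

_PROB_ATOL = 1e-6


def _check_probs(probs: np.ndarray, B: int) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.shape[-1] != B:
        raise ValueError(f"probability vector of length {probs.shape[-1]} != num_bins {B}")
    if np.any(probs < -_PROB_ATOL):
        raise ValueError("probabilities must be nonnegative")
    sums = probs.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=_PROB_ATOL):
        raise ValueError("probabilities must sum to 1")
    return probs


@dataclass(frozen=True)
class BinCodec:
    """Equal-width binning of the value range [lo, hi] into ``num_bins`` bins."""

    num_bins: int
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.num_bins < 2:
            raise ValueError("num_bins must be >= 2")
        if not self.hi > self.lo:
            raise ValueError(f"degenerate range: hi ({self.hi}) must exceed lo ({self.lo})")

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.num_bins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.num_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    # -- encoding ---------------------------------------------------------

    def encode(self, value) -> np.ndarray | int:
        """Bin index of ``value`` (scalar or array).

        Intervals are half-open ``[edge_i, edge_{i+1})`` with the final bin
        closed on the right.  Out-of-range values clamp to the edge bins
        (bin 0 below ``lo``, bin ``B-1`` above ``hi``), so chaotic test-time
        excursions beyond the training range never fail.
        """
        v = np.asarray(value, dtype=float)
        if np.any(np.isnan(v)):
            raise ValueError("cannot encode NaN values")
        idx = np.floor((v - self.lo) / self.width).astype(int)
        idx = np.clip(idx, 0, self.num_bins - 1)
        if np.ndim(value) == 0:
            return int(idx)
        return idx

    def encode_onehot(self, value) -> np.ndarray:
        """One-hot categorical encoding of ``value`` over the bins."""
        idx = np.atleast_1d(self.encode(value))
        out = np.zeros((idx.size, self.num_bins))
        out[np.arange(idx.size), idx] = 1.0
        if np.ndim(value) == 0:
            return out[0]
        return out

    # -- decoding ---------------------------------------------------------

    def decode_argmax(self, probs) -> float | np.ndarray:
        """Center of the highest-probability bin (ties break to the lower index)."""
        probs = _check_probs(probs, self.num_bins)
        idx = np.argmax(probs, axis=-1)  # np.argmax takes the first (lowest) max
        out = self.centers[idx]
        return float(out) if probs.ndim == 1 else out

    def decode_expect(self, probs) -> float | np.ndarray:
        """Expectation of the bin-center value under the distribution."""
        probs = _check_probs(probs, self.num_bins)
        out = probs @ self.centers
        return float(out) if probs.ndim == 1 else out

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({"num_bins": self.num_bins, "lo": self.lo, "hi": self.hi})

    @classmethod
    def from_json(cls, doc: str) -> "BinCodec":
        d = json.loads(doc)
        return cls(num_bins=int(d["num_bins"]), lo=float(d["lo"]), hi=float(d["hi"]))


def fit_bins(train_values, B: int, margin: float = 0.0) -> BinCodec:
    """Fit an equal-width codec spanning the range of the training targets.

    ``lo``/``hi`` are the min/max of ``train_values`` optionally padded
    symmetrically by ``margin`` (a fraction of the range).  The codec is fit
    on training targets only; test-time excursions outside the range clamp
    to the edge bins at encode time.
    """
    v = np.asarray(train_values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("need at least 2 distinct training values to fit bins")
    if B < 2:
        raise ValueError("B must be >= 2")
    lo, hi = float(np.min(v)), float(np.max(v))
    pad = margin * (hi - lo)
    return BinCodec(num_bins=int(B), lo=lo - pad, hi=hi + pad)
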