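"""Sliding-window dataset construction and chronological splits.

A trace sampled every ``dt`` seconds is converted into supervised pairs: the
input ``x_i`` holds ``m`` consecutive samples (default 15, about 3 s at 5 Hz)
and the labels ``y_{i,1..J}`` are the next ``J`` samples, i.e. the horizons
``dt, 2*dt, ..., J*dt`` ahead of the window's last sample (its *anchor*).
Successive windows advance by one sample.

Splits are chronological: labels are future samples, so shuffled splits would
leak test information into training.  The final 20% of the training pool (its
most recent windows) serves as the validation block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import InputError, ParameterError
from .trace_sim import Trace

__all__ = ["WindowSet", "SplitSpec", "make_windows", "split_windows"]


@dataclass
class WindowSet:
    """Paired (input window, multi-horizon label) matrices for regression."""

    inputs: np.ndarray       # (N, m) mm
    labels: np.ndarray       # (N, J) mm; column k-1 is the k*dt-ahead label
    anchor_times: np.ndarray  # (N,) s; time of each window's last sample
    m: int = 15
    J: int = 3
    dt: float = 0.2

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        self.anchor_times = np.asarray(self.anchor_times, dtype=float)
        if self.inputs.ndim != 2 or self.inputs.shape[1] != self.m:
            raise InputError("inputs must be an (N, m) matrix")
        n = self.inputs.shape[0]
        if n < 1:
            raise InputError("a WindowSet needs at least one row")
        if self.labels.shape != (n, self.J):
            raise InputError("labels must be an (N, J) matrix")
        if self.anchor_times.shape != (n,):
            raise InputError("anchor_times must have one entry per row")

    @property
    def n(self) -> int:
        return int(self.inputs.shape[0])

    def horizon_labels(self, j: int) -> np.ndarray:
        """Labels for horizon ``j`` samples ahead (1-based, j <= J)."""
        if not 1 <= j <= self.J:
            raise ParameterError(f"horizon j={j} outside 1..{self.J}")
        return self.labels[:, j - 1]

    def rows(self, idx) -> "WindowSet":
        return WindowSet(self.inputs[idx], self.labels[idx],
                         self.anchor_times[idx], m=self.m, J=self.J, dt=self.dt)


@dataclass(frozen=True)
class SplitSpec:
    """Chronological train/validation/test partition fractions."""

    train_frac: float = 0.70
    test_frac: float = 0.30
    val_frac_of_train: float = 0.20
    contiguous: bool = True

    def __post_init__(self) -> None:
        for f in (self.train_frac, self.test_frac, self.val_frac_of_train):
            if not 0 < f < 1:
                raise ParameterError("split fractions must lie in (0, 1)")
        if abs(self.train_frac + self.test_frac - 1.0) > 1e-9:
            raise ParameterError("train_frac + test_frac must equal 1")
        if not self.contiguous:
            raise ParameterError(
                "only chronological (contiguous) splits are supported: "
                "labels are future samples, shuffling leaks")


def make_windows(trace: Trace, channel: str = "si", m: int = 15,
                 J: int = 3) -> WindowSet:
    """Segment a trace channel into N = len - m - J + 1 sliding windows."""
    if m < 1 or J < 1:
        raise ParameterError("m and J must be >= 1")
    y = trace.channel(channel)
    n = y.size
    if n < m + J:
        raise InputError(f"trace too short: need >= {m + J} samples, got {n}")
    windows = sliding_window_view(y, m + J)  # rows advance one sample
    inputs = windows[:, :m].copy()
    labels = windows[:, m:].copy()
    anchors = trace.times[m - 1:n - J].copy()
    return WindowSet(inputs, labels, anchors, m=m, J=J, dt=trace.dt)


def split_windows(ws: WindowSet, spec: SplitSpec = SplitSpec()):
    """Partition a WindowSet chronologically into (train, validation, test).

    Sizes use a floor rule: ``test = floor(N * test_frac)``, the remainder is
    the training pool, ``val = floor(pool * val_frac_of_train)`` taken from
    the end (most recent windows) of the pool, remainder to train.
    """
    n = ws.n
    if n < 10:
        raise InputError(f"need at least 10 windows to split, got {n}")
    n_test = int(np.floor(n * spec.test_frac))
    pool = n - n_test
    n_val = int(np.floor(pool * spec.val_frac_of_train))
    n_train = pool - n_val
    train = ws.rows(slice(0, n_train))
    val = ws.rows(slice(n_train, pool))
    test = ws.rows(slice(pool, n))
    return train, val, test
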