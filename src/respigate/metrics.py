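"""Amplitude and temporal accuracy metrics for gated-beam control.

Amplitude metrics (MAE, RMSE, R^2) score the predicted motion trace against
the observed one.  Temporal metrics score the *control* behaviour:

* crossing error -- |Delta t| between each predicted threshold crossing and
  the nearest same-direction reference crossing (ms);
* gating error -- the same quantity between the transitions of the
  generated gating signal and the ideal signal (which leads each true
  crossing by the system latency);
* gating accuracy -- the percentage of therapy time during which the
  generated and ideal binary signals agree, computed as an exact interval
  symmetric difference (no time binning).

Event pairing is a one-to-one nearest match restricted to same-direction
events within a pairing window (default: half a breathing period), so a
predicted event can never be scored against a crossing from another cycle.
Unpaired (missed or spurious) events are counted separately and penalize
gating accuracy through the overlap, not the error mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateResultError, InputError
from .gating import CrossingEvent, GatingSignal

__all__ = [
    "MetricsReport",
    "PairedErrors",
    "mae",
    "rmse",
    "r2",
    "crossing_errors",
    "gating_errors",
    "gating_accuracy",
    "compare_models",
]


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.size != yhat.size:
        raise InputError("need equal-length, non-empty vectors")
    return y, yhat


def mae(y, yhat) -> float:
    """Mean absolute error (mm)."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y, yhat) -> float:
    """Root-mean-square error (mm)."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r2(y, yhat) -> float:
    """Coefficient of determination, with the observed mean as baseline."""
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateResultError("R^2 undefined: observed variance is zero")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


@dataclass
class PairedErrors:
    """Per-event |Delta t| (ms) plus counts of unmatched events."""

    errors_ms: np.ndarray
    n_unmatched_pred: int = 0
    n_unmatched_ref: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.errors_ms)) if self.errors_ms.size else np.nan

    @property
    def sd(self) -> float:
        return float(np.std(self.errors_ms, ddof=1)) if self.errors_ms.size > 1 else 0.0


def _match_events(pred: Sequence, ref: Sequence, window: float) -> PairedErrors:
    """Greedy one-to-one nearest matching within same-direction subsets."""
    errors = []
    n_up = n_ur = 0
    for direction in ("on", "off"):
        p = [e.time for e in pred if e.direction == direction]
        r = [e.time for e in ref if e.direction == direction]
        cand = sorted(
            (abs(tp - tr), i, k)
            for i, tp in enumerate(p) for k, tr in enumerate(r)
            if abs(tp - tr) <= window
        )
        used_p, used_r = set(), set()
        for d, i, k in cand:
            if i in used_p or k in used_r:
                continue
            used_p.add(i)
            used_r.add(k)
            errors.append(d * 1000.0)
        n_up += len(p) - len(used_p)
        n_ur += len(r) - len(used_r)
    return PairedErrors(np.array(sorted(errors)), n_up, n_ur)


def crossing_errors(pred_events, ref_events,
                    pairing_window: float = 2.0) -> PairedErrors:
    """Temporal errors between predicted and reference threshold crossings."""
    return _match_events(pred_events, ref_events, pairing_window)


def _signal_events(sig: GatingSignal) -> list:
    # direction keyed on state change; matches 'on'=beam-on for on-below gating
    return [CrossingEvent(t, "on" if s == 1 else "off")
            for t, s in sig.transitions]


def gating_errors(pred_signal: GatingSignal, ideal_signal: GatingSignal,
                  pairing_window: float = 2.0) -> PairedErrors:
    """Temporal errors between generated and ideal signal transitions."""
    return _match_events(_signal_events(pred_signal),
                         _signal_events(ideal_signal), pairing_window)


def gating_accuracy(pred_signal: GatingSignal, ideal_signal: GatingSignal,
                    total_time: float | None = None) -> float:
    """Percentage of therapy time with generated == ideal beam state.

    Exact sweep over the union of transition times: 100 * (1 - symmetric
    difference duration / total time).  Both signals must share a common
    span start; ``total_time`` defaults to the overlapping span length.
    """
    t0 = max(pred_signal.span[0], ideal_signal.span[0])
    if total_time is None:
        total_time = min(pred_signal.span[1], ideal_signal.span[1]) - t0
    if total_time <= 0:
        raise InputError("total_time must be > 0")
    t1 = t0 + total_time
    edges = np.unique(np.concatenate([
        [t0, t1],
        [t for t in pred_signal.times if t0 < t < t1],
        [t for t in ideal_signal.times if t0 < t < t1],
    ]))
    mids = 0.5 * (edges[:-1] + edges[1:])
    mismatch = pred_signal.state_at(mids) != ideal_signal.state_at(mids)
    diff = float(np.sum(np.diff(edges)[mismatch]))
    return 100.0 * (1.0 - diff / total_time)


def compare_models(metric_a, metric_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-patient metrics."""
    a = np.asarray(metric_a, dtype=float).ravel()
    b = np.asarray(metric_b, dtype=float).ravel()
    if a.size != b.size or a.size < 5:
        raise InputError("need paired vectors of equal length >= 5")
    if np.all(a == b):
        raise DegenerateResultError("all paired differences are zero")
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)


@dataclass
class MetricsReport:
    """Amplitude + temporal metrics for one (trace, predictor, window) run."""

    mae: float
    rmse: float
    r2: float
    crossing_error_mean: float  # ms
    crossing_error_sd: float    # ms
    gating_error_mean: float    # ms
    gating_error_sd: float      # ms
    gating_accuracy: float      # %
    n_events: int
    total_time: float           # s
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.mae) and np.isfinite(self.rmse) \
                and self.mae > self.rmse + 1e-12:
            raise InputError("MAE cannot exceed RMSE")
        if not -1e-9 <= self.gating_accuracy <= 100 + 1e-9:
            raise InputError("gating accuracy must lie in [0, 100]")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "mae", "rmse", "r2", "crossing_error_mean", "crossing_error_sd",
            "gating_error_mean", "gating_error_sd", "gating_accuracy",
            "n_events", "total_time")}
        d.update(self.extra)
        return d

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(o)

        Path(path).write_text(json.dumps(self.to_dict(), indent=1,
                                         default=default))

    @classmethod
    def from_json(cls, path) -> "MetricsReport":
        import json
        from pathlib import Path
        d = json.loads(Path(path).read_text())
        core = {k: d.pop(k) for k in (
            "mae", "rmse", "r2", "crossing_error_mean", "crossing_error_sd",
            "gating_error_mean", "gating_error_sd", "gating_accuracy",
            "n_events", "total_time")}
        return cls(extra=d, **core)
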