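"""Threshold-crossing estimation and beam-gating signal generation.

The beam is allowed on while the target sits below an amplitude threshold
``Th`` (the stagnant end-exhale phase).  Because the delivery chain has an
end-to-end latency (0.5 s here), the controller must toggle the beam *ahead*
of each threshold crossing.  From the two-horizon forecasts
``(yhat_{j-1}, yhat_j)`` made at decision time ``T_i`` the crossing time is
estimated by linear interpolation,

    That_cross = (Th - yhat_j) / (yhat_j - yhat_{j-1}) * dt + T_i + j*dt,

algebraically the standard interpolation between the points
``(T_i + (j-1)dt, yhat_{j-1})`` and ``(T_i + j*dt, yhat_j)``.  A toggle is
scheduled at ``That_cross - latency`` when either

* condition A: ``Th`` is bracketed between the two forecasts, or
* condition B: the extrapolated crossing falls within ``dt_max`` (default
  0.1 s) beyond the far horizon,

with a same-direction refractory to deduplicate a crossing seen by two
consecutive windows.  Scheduling is causal: a toggle that would fall before
the current decision time fires at the decision time instead, and one that
would fall before the stream even started is dropped (the beam simply stays
off through a cold start).

The *ideal* gating signal leads every true crossing by exactly the latency;
it is the gold standard against which generated signals are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError, ParameterError
from .trace_sim import Trace

__all__ = [
    "GatingConfig",
    "CrossingEvent",
    "GatingSignal",
    "estimate_threshold",
    "predicted_crossing_time",
    "reference_crossings",
    "signal_from_crossings",
    "ideal_gating",
    "crossing_time_gating",
    "generate_gating",
]


@dataclass(frozen=True)
class GatingConfig:
    """Controller configuration (times in s, threshold in mm)."""

    dt: float = 0.2
    latency: float = 0.5
    horizon_j: int = 3
    dt_max: float = 0.1
    threshold: float | None = None
    beam_on_below: bool = True
    refractory: float = 0.5

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if not 0 < self.dt_max <= self.dt:
            raise ParameterError("need 0 < dt_max <= dt")
        if self.latency <= 0:
            raise ParameterError("latency must be > 0")
        if self.horizon_j < 2:
            raise ParameterError("horizon_j must be >= 2")

    @property
    def window(self) -> float:
        """Prediction window in seconds (horizon_j * dt)."""
        return self.horizon_j * self.dt


@dataclass(frozen=True)
class CrossingEvent:
    """A threshold crossing: 'on' = trace crosses below the threshold."""

    time: float
    direction: str  # 'on' | 'off'

    def __post_init__(self) -> None:
        if self.direction not in ("on", "off"):
            raise ParameterError("direction must be 'on' or 'off'")


@dataclass
class GatingSignal:
    """Binary beam-state step function given by ordered state transitions."""

    transitions: list  # [(time s, new_state 0|1), ...]
    span: tuple  # (start s, end s)
    initial_state: int = 0
    crossings: list = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        t0, t1 = self.span
        if t1 <= t0:
            raise InputError("span end must exceed span start")
        state = self.initial_state
        last = -np.inf
        for t, s in self.transitions:
            if t <= last:
                raise InputError("transition times must be strictly increasing")
            if s == state:
                raise InputError("consecutive transition states must differ")
            if not t0 <= t <= t1:
                raise InputError("transition outside signal span")
            last, state = t, s

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.transitions])

    @property
    def states(self) -> np.ndarray:
        return np.array([s for _, s in self.transitions], dtype=int)

    def state_at(self, t) -> np.ndarray:
        """Beam state at time(s) ``t`` (piecewise-constant, right-continuous)."""
        t = np.asarray(t, dtype=float)
        if self.transitions:
            idx = np.searchsorted(self.times, t, side="right")
            states = np.concatenate([[self.initial_state], self.states])
            out = states[idx]
        else:
            out = np.full(t.shape, self.initial_state, dtype=int)
        return out if out.shape else int(out)

    def beam_on_fraction(self) -> float:
        """Fraction of the span with the beam on (duty cycle)."""
        t0, t1 = self.span
        edges = np.concatenate([[t0], self.times, [t1]])
        states = np.concatenate([[self.initial_state], self.states])
        return float(np.sum(np.diff(edges) * states) / (t1 - t0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.transitions, columns=["time", "state"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def estimate_threshold(trace: Trace, burn_in: float = 30.0,
                       channel: str = "si") -> float:
    """Gating threshold: mean of the channel over the burn-in segment."""
    if burn_in <= 0 or burn_in > trace.duration + trace.dt:
        raise InputError("burn-in must be positive and within the trace")
    mask = trace.times < trace.times[0] + burn_in
    if not mask.any():
        raise InputError("empty burn-in window")
    return float(trace.channel(channel)[mask].mean())


def predicted_crossing_time(y_prev: float, y_last: float, threshold: float,
                            t_i: float, j: int = 3, dt: float = 0.2,
                            dt_max: float = 0.1) -> float | None:
    """Interpolated threshold-crossing time from a two-horizon forecast.

    Returns the crossing time when the threshold is bracketed between the
    forecasts (condition A) or the extrapolated crossing lies within
    ``dt_max`` beyond the far horizon ``t_i + j*dt`` (condition B); ``None``
    otherwise.  A flat pair exactly at the threshold returns the near
    horizon time (tie rule).
    """
    if y_prev == y_last:
        if threshold == y_prev:
            return t_i + (j - 1) * dt
        return None
    t_cross = (threshold - y_last) / (y_last - y_prev) * dt + t_i + j * dt
    far = t_i + j * dt
    lo, hi = (y_prev, y_last) if y_prev <= y_last else (y_last, y_prev)
    if lo <= threshold <= hi:
        return t_cross
    if far < t_cross <= far + dt_max:
        return t_cross
    return None


def reference_crossings(trace: Trace, threshold: float,
                        channel: str = "si") -> list:
    """Gold-standard crossing events by interpolating consecutive samples.

    A sample lying exactly on the threshold is resolved by the tie rule:
    the crossing is assigned to that sample's time, with the direction taken
    from the following movement.  Events alternate by construction.
    """
    y = trace.channel(channel)
    t = trace.times
    events = []
    side = None          # 'above' | 'below', last strict side seen
    side_idx = None
    for k in range(y.size):
        if y[k] > threshold:
            cur = "above"
        elif y[k] < threshold:
            cur = "below"
        else:
            continue  # exactly at threshold; wait for the next strict side
        if side is not None and cur != side:
            p = side_idx
            if k == p + 1:
                tc = t[p] + (t[k] - t[p]) * (threshold - y[p]) / (y[k] - y[p])
            else:
                tc = t[p + 1]  # tie rule: first sample that sat on Th
            events.append(CrossingEvent(float(tc),
                                        "on" if cur == "below" else "off"))
        side, side_idx = cur, k
    return events


def signal_from_crossings(events, span, lead: float = 0.0,
                          beam_on_below: bool = True,
                          initial_state: int | None = None) -> GatingSignal:
    """Build a gating signal whose toggles lead each crossing by ``lead`` s.

    Transitions falling before the span start are clipped to it (colliding
    clipped transitions keep only the last).  When ``initial_state`` is not
    given it is inferred as the complement of the first transition so the
    signal is a genuine step there, or 0 for an empty event list.
    """
    t0, t1 = span
    raw = []
    for e in events:
        state = 1 if (e.direction == "on") == beam_on_below else 0
        time = max(e.time - lead, t0)
        if time > t1:
            continue
        raw.append((time, state))
    # collapse collisions at the clipped start
    cleaned = []
    for time, state in raw:
        if cleaned and time <= cleaned[-1][0]:
            cleaned[-1] = (cleaned[-1][0], state)
        else:
            cleaned.append((time, state))
    # drop no-op transitions after collapsing
    if initial_state is None:
        initial_state = 1 - cleaned[0][1] if cleaned else 0
    final = []
    state = initial_state
    for time, s in cleaned:
        if s != state:
            final.append((time, s))
            state = s
    return GatingSignal(final, (t0, t1), initial_state=initial_state,
                        crossings=list(events))


def ideal_gating(events, cfg: GatingConfig, span,
                 initial_state: int | None = None) -> GatingSignal:
    """Ideal signal: each crossing led by exactly the system latency."""
    return signal_from_crossings(events, span, lead=cfg.latency,
                                 beam_on_below=cfg.beam_on_below,
                                 initial_state=initial_state)


def crossing_time_gating(events, cfg: GatingConfig, span) -> GatingSignal:
    """No-prediction baseline: toggles exactly at the crossing times."""
    return signal_from_crossings(events, span, lead=0.0,
                                 beam_on_below=cfg.beam_on_below,
                                 initial_state=0)


def generate_gating(stream, cfg: GatingConfig, span=None) -> GatingSignal:
    """Run the gating controller over a prediction stream.

    ``stream`` yields time-ordered ``(T_i, yhat_prev, yhat_last)`` triples
    spaced by ``cfg.dt``.  Returns the generated :class:`GatingSignal`; the
    crossing estimates that produced its transitions are attached as
    ``signal.crossings`` (used for crossing-error metrics).
    """
    if cfg.threshold is None:
        raise ParameterError("cfg.threshold must be set")
    stream = list(stream)
    if not stream:
        raise InputError("empty prediction stream")
    anchors = np.array([s[0] for s in stream])
    if np.any(np.diff(anchors) <= 0):
        raise InputError("prediction stream must be time-ordered")
    t_start = float(anchors[0])
    t_end = float(anchors[-1] + cfg.window + cfg.dt_max)
    if span is None:
        span = (t_start, t_end)

    # Each entry: [time, state, direction, first_seen (decision time of the
    # window that opened this toggle), estimate].  A later window re-seeing
    # the same crossing (same direction, estimate within the refractory)
    # refines the pending toggle's timing -- it cannot move it before the
    # decision time that opened it.
    emitted: list[list] = []
    state = 0
    last_est = {"on": -np.inf, "off": -np.inf}
    # with over-prediction (window >= latency) the estimate leads the
    # crossing far enough that the toggle fires at estimate - latency; with
    # under-prediction it cannot fire before the decision that opened it
    over_predicting = cfg.window >= cfg.latency
    for t_i, y_prev, y_last in stream:
        tc = predicted_crossing_time(y_prev, y_last, cfg.threshold, t_i,
                                     j=cfg.horizon_j, dt=cfg.dt,
                                     dt_max=cfg.dt_max)
        if tc is None or y_prev == y_last:
            continue  # no crossing, or flat tie (no slope -> no trigger)
        direction = "on" if y_last < y_prev else "off"
        new_state = 1 if (direction == "on") == cfg.beam_on_below else 0
        duplicate = abs(tc - last_est[direction]) < cfg.refractory
        last_est[direction] = tc
        if duplicate:
            # revise the pending toggle if it is still the most recent one
            if emitted and emitted[-1][2] == direction:
                rec = emitted[-1]
                floor = t_start if over_predicting else max(rec[3], t_start)
                rec[0] = float(max(tc - cfg.latency, floor))
                rec[4] = float(tc)
            continue
        if new_state == state:
            continue
        if tc - cfg.latency < t_start:
            continue  # cold start: no window could have acted with full lead
        emit = tc - cfg.latency if over_predicting else max(tc - cfg.latency,
                                                            t_i)
        if emit > span[1]:
            continue
        emitted.append([float(emit), new_state, direction, float(t_i),
                        float(tc)])
        state = new_state

    transitions = []
    acted = []
    last_t = -np.inf
    for time, new_state, direction, _, est in emitted:
        if time <= last_t:  # revisions cannot reorder; guard regardless
            time = float(np.nextafter(last_t, np.inf))
        transitions.append((time, new_state))
        acted.append(CrossingEvent(est, direction))
        last_t = time
    return GatingSignal(transitions, span, initial_state=0, crossings=acted)
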