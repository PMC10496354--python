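"""Model/Results objects tying the pipeline together.

:class:`GatingControl` is built from a respiratory :class:`~respigate.trace_sim.Trace`
plus a choice of predictor and prediction window; ``fit()`` runs the full
chain -- threshold estimation, windowing, predictor fitting (batch or
adaptive online), crossing-time interpolation, gating-signal generation --
and returns a :class:`GatingControlResults` carrying the fitted
coefficients, the generated and ideal signals, amplitude and temporal
metrics, and a ``summary()`` table.

Two training regimes are supported, mirroring how such a controller is
evaluated offline versus deployed online:

* static (``adaptive=False``): the predictor is fitted once on the first
  70% of windows (or on ``training_seconds`` of data) and evaluated on the
  remainder;
* adaptive (``adaptive=True``): the predictor is fitted on a short burn-in
  (default 30 s) and then refitted continuously as each label is observed,
  with gating running online from the end of the burn-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError, ParameterError
from .gating import (GatingConfig, GatingSignal, crossing_time_gating,
                     estimate_threshold, generate_gating, ideal_gating,
                     reference_crossings)
from .metrics import (MetricsReport, crossing_errors, gating_accuracy,
                      gating_errors, mae, r2, rmse)
from .predictors import (AdaptiveLinearPredictor, PredictorModel, dummy_pair,
                         fit_predictor, predict_pair)
from .trace_sim import Trace
from .windowing import SplitSpec, make_windows, split_windows

__all__ = ["GatingControl", "GatingControlResults", "burnin_sweep"]

_METHODS = ("ols", "linear", "ridge", "l2l1", "kalman", "dummy", "oracle")


class GatingControl:
    """Patient-specific gated-beam control model for one motion trace."""

    def __init__(self, trace: Trace, *, channel: str = "si",
                 method: str = "ols", window: float = 0.6, m: int = 15,
                 adaptive: bool = False, burn_in: float = 30.0,
                 training_seconds: float | None = None,
                 refit_every: int = 1, latency: float = 0.5,
                 dt_max: float = 0.1, refractory: float = 0.5,
                 beam_on_below: bool = True, split: SplitSpec | None = None,
                 threshold_burn_in: float | None = None):
        if method not in _METHODS:
            raise ParameterError(f"method must be one of {_METHODS}")
        self.trace = trace
        self.channel = channel
        self.method = "ols" if method == "linear" else method
        self.m = m
        self.adaptive = adaptive
        self.burn_in = burn_in
        self.threshold_burn_in = (burn_in if threshold_burn_in is None
                                  else threshold_burn_in)
        self.training_seconds = training_seconds
        self.refit_every = refit_every
        self.split = split or SplitSpec()
        dt = trace.dt
        j = int(round(window / dt))
        if not np.isclose(j * dt, window, atol=1e-9) or j < 2:
            raise ParameterError(
                f"window {window} s is not an integer multiple >= 2 of dt={dt}")
        self.horizon_j = j
        self._cfg_kwargs = dict(dt=dt, latency=latency, horizon_j=j,
                                dt_max=dt_max, refractory=refractory,
                                beam_on_below=beam_on_below)
        n_needed = int(round(burn_in / dt)) + m + j
        if len(trace) < n_needed:
            raise InputError(
                f"trace too short: {len(trace)} samples < burn-in + m + J "
                f"= {n_needed}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GatingControl":
        """Build from a DataFrame with columns time, si, ap, lr[, total]."""
        from .trace_sim import total_motion
        total = (df["total"].to_numpy(float) if "total" in df.columns else
                 total_motion(df["si"], df["ap"], df["lr"]))
        trace = Trace(df["time"].to_numpy(float), df["si"].to_numpy(float),
                      df["ap"].to_numpy(float), df["lr"].to_numpy(float),
                      total)
        return cls(trace, **kwargs)

    # -- internal ----------------------------------------------------------

    def _static_stream(self):
        """(stream, truth, predictor) for the batch-trained regimes."""
        ws = make_windows(self.trace, self.channel, self.m, J=self.horizon_j)
        if self.training_seconds is not None:
            # training pairs are those fully observed (labels included)
            # within the first `training_seconds` -- the adaptive burn-in
            # buffer, so static-with-burn-in and refit-disabled adaptive
            # models coincide
            cut = self.trace.times[0] + self.training_seconds
            n_train = int(np.sum(ws.anchor_times + ws.J * ws.dt
                                 < cut - 1e-9))
            if n_train < self.m:
                raise InputError("training segment holds too few windows")
            train = ws.rows(slice(0, n_train))
            test = ws.rows(slice(n_train, ws.n))
        else:
            tr, val, test = split_windows(ws, self.split)
            # hyperparameters are chosen internally (LOOCV/GCV); the final
            # coefficients use the whole 70% training pool
            train = ws.rows(slice(0, tr.n + val.n))
        if test.n == 0:
            raise InputError("no evaluation windows left after training cut")
        j = self.horizon_j
        truth = np.column_stack([test.horizon_labels(j - 1),
                                 test.horizon_labels(j)])
        if self.method == "oracle":
            preds = truth.copy()
            model = PredictorModel(None, None, horizon_j=j, method="oracle",
                                   n_train=0, m=self.m, dt=ws.dt)
        elif self.method == "dummy":
            preds = np.column_stack([test.inputs[:, -1], test.inputs[:, -1]])
            model = PredictorModel(None, None, horizon_j=j, method="dummy",
                                   n_train=0, m=self.m, dt=ws.dt)
        else:
            model = fit_predictor(train, self.method, horizon_j=j)
            if self.method == "kalman":
                preds = np.array([predict_pair(model, x) for x in test.inputs])
            else:
                preds = np.column_stack([test.inputs @ model.beta_prev,
                                         test.inputs @ model.beta_last])
        stream = list(zip(test.anchor_times, preds[:, 0], preds[:, 1]))
        return stream, truth, model

    def _adaptive_stream(self):
        if self.method not in ("ols", "oracle", "dummy"):
            raise ParameterError(
                "adaptive mode supports the least-squares predictor "
                "(method='ols') and the dummy/oracle baselines")
        j = self.horizon_j
        y = self.trace.channel(self.channel)
        t = self.trace.times
        burn_samples = int(round(self.burn_in / self.trace.dt))
        if self.method == "ols":
            ap = AdaptiveLinearPredictor(self.m, j, burn_samples,
                                         self.refit_every, self.trace.dt)
            stream, truth = [], []
            for k in range(t.size):
                p = ap.step(t[k], y[k])
                if p is not None and k + j < t.size:
                    stream.append((t[k], p[0], p[1]))
                    truth.append((y[k + j - 1], y[k + j]))
            return stream, np.asarray(truth), ap.model
        # baselines share the adaptive evaluation span
        stream, truth = [], []
        for k in range(burn_samples, t.size - j):
            if self.method == "oracle":
                stream.append((t[k], y[k + j - 1], y[k + j]))
            else:
                stream.append((t[k], *dummy_pair(y[max(0, k - self.m + 1):k + 1])))
            truth.append((y[k + j - 1], y[k + j]))
        model = PredictorModel(None, None, horizon_j=j, method=self.method,
                               n_train=0, m=self.m, dt=self.trace.dt)
        return stream, np.asarray(truth), model

    # -- fitting -----------------------------------------------------------

    def fit(self, eval_start: float | None = None) -> "GatingControlResults":
        """Run the full pipeline and return the results object."""
        trace = self.trace
        threshold = estimate_threshold(trace, self.threshold_burn_in,
                                       self.channel)
        cfg = GatingConfig(threshold=threshold, **self._cfg_kwargs)

        if self.adaptive:
            stream, truth, predictor = self._adaptive_stream()
        else:
            stream, truth, predictor = self._static_stream()
        if eval_start is not None:
            keep = [i for i, s in enumerate(stream) if s[0] >= eval_start]
            if not keep:
                raise InputError("eval_start leaves no prediction windows")
            stream = [stream[i] for i in keep]
            truth = truth[keep]
        if len(stream) < 2:
            raise InputError("evaluation stream too short")

        span = (stream[0][0], float(trace.times[-1]))
        ref_all = reference_crossings(trace, threshold, self.channel)
        ref = [e for e in ref_all if span[0] < e.time <= span[1]]
        ideal = ideal_gating(ref, cfg, span)

        if self.method == "dummy":
            signal = crossing_time_gating(ref, cfg, span)
        else:
            signal = generate_gating(stream, cfg, span=span)

        pairing = _pairing_window(ref)
        cerr = crossing_errors(signal.crossings, ref, pairing)
        gerr = gating_errors(signal, ideal, pairing)
        acc = gating_accuracy(signal, ideal)

        yhat = np.array([s[2] for s in stream])
        ytrue = truth[:, 1]
        try:
            r2_val = r2(ytrue, yhat)
        except Exception:
            r2_val = np.nan
        report = MetricsReport(
            mae=mae(ytrue, yhat), rmse=rmse(ytrue, yhat), r2=r2_val,
            crossing_error_mean=cerr.mean, crossing_error_sd=cerr.sd,
            gating_error_mean=gerr.mean, gating_error_sd=gerr.sd,
            gating_accuracy=acc, n_events=len(ref),
            total_time=span[1] - span[0],
            extra={"method": self.method, "adaptive": self.adaptive,
                   "window_s": self.horizon_j * trace.dt,
                   "threshold_mm": threshold, "lambda": predictor.lam,
                   "n_unmatched_pred": cerr.n_unmatched_pred +
                   gerr.n_unmatched_pred,
                   "label": trace.label},
        )
        return GatingControlResults(
            model=self, predictor=predictor, config=cfg, threshold=threshold,
            stream=stream, truth=truth, signal=signal, ideal=ideal,
            reference_events=ref, report=report, span=span,
            pairing_window=pairing,
            crossing_err=cerr, gating_err=gerr)


def _pairing_window(ref_events) -> float:
    """Half the typical breathing period, estimated from crossing spacing."""
    on_times = [e.time for e in ref_events if e.direction == "on"]
    if len(on_times) >= 3:
        return float(np.median(np.diff(on_times)) / 2.0)
    return 2.0


@dataclass
class GatingControlResults:
    """Fitted gating-control pipeline: estimates, signals and metrics."""

    model: GatingControl
    predictor: PredictorModel
    config: GatingConfig
    threshold: float
    stream: list
    truth: np.ndarray
    signal: GatingSignal
    ideal: GatingSignal
    reference_events: list
    report: MetricsReport
    span: tuple
    pairing_window: float
    crossing_err: object
    gating_err: object

    def predictions_frame(self) -> pd.DataFrame:
        j = self.config.horizon_j
        return pd.DataFrame({
            "anchor_time": [s[0] for s in self.stream],
            f"yhat_{j - 1}": [s[1] for s in self.stream],
            f"yhat_{j}": [s[2] for s in self.stream],
            f"y_{j - 1}": self.truth[:, 0],
            f"y_{j}": self.truth[:, 1],
        })

    def summary(self) -> str:
        r = self.report
        m = self.model
        lines = [
            "        Gated-Beam Control Results",
            "=" * 46,
            f"method:            {m.method}"
            f"{' (adaptive)' if m.adaptive else ''}",
            f"prediction window: {m.horizon_j * m.trace.dt:.1f} s "
            f"(j={m.horizon_j})",
            f"channel / m:       {m.channel} / {m.m} taps",
            f"latency:           {self.config.latency:.2f} s",
            f"threshold:         {self.threshold:.2f} mm "
            f"(burn-in {m.burn_in:.0f} s mean)",
            f"lambda:            {self.predictor.lam:.4g}",
            f"evaluation span:   {self.span[0]:.1f}-{self.span[1]:.1f} s "
            f"({r.n_events} crossings)",
            "-" * 46,
            f"MAE:               {r.mae:.3f} mm",
            f"RMSE:              {r.rmse:.3f} mm",
            f"R^2:               {r.r2:.4f}",
            f"crossing error:    {r.crossing_error_mean:.0f} +/- "
            f"{r.crossing_error_sd:.0f} ms",
            f"gating error:      {r.gating_error_mean:.0f} +/- "
            f"{r.gating_error_sd:.0f} ms",
            f"gating accuracy:   {r.gating_accuracy:.1f} %",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Trace, threshold and the generated vs ideal gating signals."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        tr = self.model.trace
        mask = (tr.times >= self.span[0]) & (tr.times <= self.span[1])
        ax.plot(tr.times[mask], tr.channel(self.model.channel)[mask],
                lw=0.8, color="0.3", label=self.model.channel.upper())
        ax.axhline(self.threshold, color="tab:red", lw=0.8, ls="--",
                   label="threshold")
        ymin = tr.channel(self.model.channel)[mask].min()
        for sig, color, name, off in ((self.ideal, "tab:green", "ideal", 0.0),
                                      (self.signal, "tab:blue", "generated",
                                       1.2)):
            t = np.concatenate([[self.span[0]], sig.times, [self.span[1]]])
            s = np.concatenate([[sig.initial_state], sig.states,
                                [sig.states[-1] if len(sig.transitions)
                                 else sig.initial_state]])
            ax.step(t, ymin - 3 - off + 1.0 * s, where="post", color=color,
                    lw=1.2, label=name)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("position (mm) / beam state")
        ax.legend(loc="upper right", fontsize=8, ncol=4)
        return ax


def burnin_sweep(traces, burn_ins, *, method: str = "ols",
                 window: float = 0.6, m: int = 15, channel: str = "si",
                 eval_start: float | None = None,
                 threshold_burn_in: float = 30.0) -> pd.DataFrame:
    """Gating accuracy of adaptive vs static training as burn-in grows.

    For each burn-in length ``b`` (seconds) every trace is run twice: with
    the adaptive online predictor (burn-in ``b``) and with a static
    predictor trained once on the first ``b`` seconds.  The gating threshold
    is estimated from a fixed ``threshold_burn_in`` segment so that only the
    predictor's training length varies across ``b``.  Returns a tidy
    DataFrame with per-(burn-in, variant) mean and quartiles of gating
    accuracy over the cohort.  Burn-ins longer than a trace are skipped with
    a warning.
    """
    if len(burn_ins) == 0:
        raise InputError("burn-in list must be non-empty")
    rows = []
    for b in burn_ins:
        accs = {"adaptive": [], "static": []}
        for trace in traces:
            if b + 5.0 >= trace.duration:
                warnings.warn(f"burn-in {b} s too long for trace "
                              f"{trace.label!r}; skipped")
                continue
            common = dict(channel=channel, method=method, window=window, m=m,
                          threshold_burn_in=threshold_burn_in)
            res_a = GatingControl(trace, adaptive=True, burn_in=b,
                                  **common).fit(eval_start=eval_start)
            res_s = GatingControl(trace, adaptive=False, burn_in=b,
                                  training_seconds=b,
                                  **common).fit(eval_start=eval_start)
            accs["adaptive"].append(res_a.report.gating_accuracy)
            accs["static"].append(res_s.report.gating_accuracy)
        for variant, vals in accs.items():
            if not vals:
                continue
            v = np.asarray(vals)
            rows.append({"burn_in_s": b, "variant": variant,
                         "mean_accuracy": v.mean(),
                         "q25": np.percentile(v, 25),
                         "q75": np.percentile(v, 75), "n": v.size})
    return pd.DataFrame(rows)
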