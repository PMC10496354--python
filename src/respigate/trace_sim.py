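"""Synthetic respiratory-motion traces.

Patient cine-MR trajectories are rarely shareable, so this module generates
quasi-periodic breathing traces with the statistical structure reported for
liver and lung motion on an MR-linac: per-cycle period and amplitude
variability, baseline drift, additive measurement noise, and a dominant
superior-inferior (SI) axis with scaled anterior-posterior (AP) and
left-right (LR) components.  The waveform within each cycle is the classic
``cos^{2n}``-type profile (implemented as ``sin^{2n}(pi u)`` over the cycle
phase ``u``), which rests near end-exhale and peaks briefly at inhale --
exactly the asymmetry that amplitude gating exploits.

Traces are uniformly sampled (default 5 Hz, i.e. 0.2 s) and carry the "3D
total motion" channel: the per-sample Euclidean norm of the (SI, AP, LR)
displacement from a reference position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError, ParameterError

__all__ = [
    "BreathingParams",
    "Trace",
    "simulate_trace",
    "total_motion",
    "load_preset",
    "params_from_preset",
    "sample_cohort_params",
    "PRESET_NAMES",
]

PRESET_NAMES = ("liver", "lung")

_CHANNELS = ("si", "ap", "lr", "total")


@dataclass(frozen=True)
class BreathingParams:
    """Parameters of the synthetic breathing-trace generator.

    Units: periods and durations in seconds, amplitudes and noise in mm,
    drift in mm/min.  ``amp_sd_frac`` is the per-cycle amplitude standard
    deviation as a fraction of the mean amplitude.  ``shape_exponent`` is the
    (even) exponent of the within-cycle profile; larger values lengthen the
    end-exhale rest.
    """

    mean_period: float = 4.0
    period_sd: float = 0.2
    mean_amp_si: float = 10.0
    mean_amp_ap: float = 3.0
    mean_amp_lr: float = 2.0
    amp_sd_frac: float = 0.05
    drift_mm_per_min: float = 0.5
    noise_sd: float = 0.2
    shape_exponent: int = 4
    duration: float = 300.0
    sample_period: float = 0.2
    seed: int = 0
    ap_lag_s: float = 0.0
    lr_lag_s: float = 0.0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.mean_period <= 0:
            raise ParameterError("mean_period must be > 0")
        if self.sample_period <= 0:
            raise ParameterError("sample_period must be > 0")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        for name in ("mean_amp_si", "mean_amp_ap", "mean_amp_lr"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.period_sd < 0 or self.amp_sd_frac < 0:
            raise ParameterError("variability parameters must be >= 0")
        if self.shape_exponent <= 0 or self.shape_exponent % 2:
            raise ParameterError("shape_exponent must be a positive even integer")


@dataclass
class Trace:
    """A uniformly sampled multi-axis respiratory trajectory (mm vs s)."""

    times: np.ndarray
    si: np.ndarray
    ap: np.ndarray
    lr: np.ndarray
    total: np.ndarray
    label: str = "trace"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("si", "ap", "lr", "total"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        if n < 2:
            raise InputError("a trace needs at least 2 samples")
        for name in ("si", "ap", "lr", "total"):
            if getattr(self, name).size != n:
                raise InputError("all trace channels must have equal length")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise InputError("times must be strictly increasing")
        if np.ptp(steps) > 1e-9:
            raise InputError("times must be uniformly spaced (to 1e-9 s)")
        if np.any(self.total < 0):
            raise InputError("total motion must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)

    def channel(self, name: str) -> np.ndarray:
        if name not in _CHANNELS:
            raise InputError(f"unknown channel {name!r}; choose from {_CHANNELS}")
        return getattr(self, name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "si": self.si, "ap": self.ap,
             "lr": self.lr, "total": self.total}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str | None = None,
                 total_reference: str = "series_mean") -> "Trace":
        df = pd.read_csv(path)
        required = {"time", "si", "ap", "lr"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"trace CSV missing columns: {sorted(missing)}")
        if "total" in df.columns:
            total = df["total"].to_numpy(float)
        else:
            total = total_motion(df["si"].to_numpy(float),
                                 df["ap"].to_numpy(float),
                                 df["lr"].to_numpy(float),
                                 reference=total_reference)
        return cls(df["time"].to_numpy(float), df["si"].to_numpy(float),
                   df["ap"].to_numpy(float), df["lr"].to_numpy(float),
                   total, label=label or Path(path).stem)


def total_motion(si, ap, lr, reference: str = "series_mean") -> np.ndarray:
    """Combine SI/AP/LR motion into the 3D total-motion amplitude.

    Per-sample Euclidean norm of the displacement of ``(si, ap, lr)`` from a
    reference position: either the first sample (``"first_sample"``) or the
    per-channel mean (``"series_mean"``).
    """
    si = np.asarray(si, dtype=float)
    ap = np.asarray(ap, dtype=float)
    lr = np.asarray(lr, dtype=float)
    if not (si.shape == ap.shape == lr.shape) or si.ndim != 1:
        raise InputError("si, ap, lr must be 1-D series of equal length")
    if reference == "first_sample":
        ref = np.array([si[0], ap[0], lr[0]])
    elif reference == "series_mean":
        ref = np.array([si.mean(), ap.mean(), lr.mean()])
    else:
        raise ParameterError("reference must be 'first_sample' or 'series_mean'")
    d = np.stack([si - ref[0], ap - ref[1], lr - ref[2]])
    return np.sqrt((d * d).sum(axis=0))


def _draw_truncated(rng, mean: float, sd: float, lower: float) -> float:
    """Normal draw truncated (by redraw) to stay above ``lower``."""
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > lower:
            return float(v)
    return max(mean, np.nextafter(lower, np.inf))  # pathological sd


def _cycles(rng, params: BreathingParams, horizon: float):
    """Cycle start times, periods and SI amplitudes covering ``horizon`` s."""
    starts, periods, amps = [], [], []
    t = 0.0
    while t <= horizon:
        p = _draw_truncated(rng, params.mean_period, params.period_sd,
                            0.5 * params.mean_period)
        a = _draw_truncated(rng, params.mean_amp_si,
                            params.amp_sd_frac * params.mean_amp_si, 0.0)
        starts.append(t)
        periods.append(p)
        amps.append(a)
        t += p
    return np.array(starts), np.array(periods), np.array(amps)


def simulate_trace(params: BreathingParams) -> Trace:
    """Generate a synthetic breathing trace; deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    n = int(np.floor(params.duration / params.sample_period)) + 1
    times = np.arange(n) * params.sample_period

    max_lag = max(params.ap_lag_s, params.lr_lag_s, 0.0)
    starts, periods, amps = _cycles(rng, params, params.duration + max_lag)

    def profile(t: np.ndarray) -> np.ndarray:
        # piecewise: cycle k spans [starts[k], starts[k]+periods[k])
        k = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, None)
        u = (t - starts[k]) / periods[k]
        return amps[k] * np.sin(np.pi * u) ** params.shape_exponent

    si = profile(times)
    ap_scale = params.mean_amp_ap / params.mean_amp_si if params.mean_amp_si else 0.0
    lr_scale = params.mean_amp_lr / params.mean_amp_si if params.mean_amp_si else 0.0
    ap = ap_scale * profile(times - params.ap_lag_s)
    lr = lr_scale * profile(times - params.lr_lag_s)

    si = si + params.drift_mm_per_min / 60.0 * times
    if params.noise_sd > 0:
        si = si + rng.normal(0.0, params.noise_sd, n)
        ap = ap + rng.normal(0.0, params.noise_sd, n)
        lr = lr + rng.normal(0.0, params.noise_sd, n)

    total = total_motion(si, ap, lr, reference="series_mean")
    return Trace(times, si, ap, lr, total, label=params.label)


# ---------------------------------------------------------------------------
# presets


def load_preset(name_or_path) -> dict:
    """Load a cohort preset ("liver", "lung", or a YAML path)."""
    if name_or_path in PRESET_NAMES:
        text = (resources.files("respigate") / "presets" /
                f"{name_or_path}.yaml").read_text()
    else:
        text = Path(name_or_path).read_text()
    preset = yaml.safe_load(text)
    if "mean_period" not in preset or "mean_amp_si" not in preset:
        raise ParameterError("preset must define mean_period and mean_amp_si")
    return preset


_PARAM_FIELDS = {f for f in BreathingParams.__dataclass_fields__}


def params_from_preset(preset: dict | str, **overrides) -> BreathingParams:
    """Build :class:`BreathingParams` from a preset's cohort-mean values."""
    if isinstance(preset, (str, Path)):
        preset = load_preset(preset)
    kw = {k: v for k, v in preset.items() if k in _PARAM_FIELDS}
    kw.update(overrides)
    return BreathingParams(**kw)


def sample_cohort_params(preset: dict | str, n: int, seed: int = 0,
                         **overrides) -> list[BreathingParams]:
    """Draw ``n`` per-patient parameter sets from a cohort preset.

    Patient-level mean period and mean SI amplitude are drawn from truncated
    normals centred on the cohort mean, with sd a quarter of the reported
    min-max span, truncated to that span; AP/LR amplitudes scale
    proportionally with the SI draw.
    """
    if isinstance(preset, (str, Path)):
        preset = load_preset(preset)
    if n < 1:
        raise ParameterError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    base = params_from_preset(preset, **overrides)
    p_lo, p_hi = preset.get("period_range", (0.6 * base.mean_period,
                                             1.5 * base.mean_period))
    a_lo, a_hi = preset.get("amp_si_range", (0.5 * base.mean_amp_si,
                                             1.8 * base.mean_amp_si))
    out = []
    for i in range(n):
        period = np.clip(rng.normal(base.mean_period, (p_hi - p_lo) / 4),
                         p_lo, p_hi)
        amp = np.clip(rng.normal(base.mean_amp_si, (a_hi - a_lo) / 4),
                      a_lo, a_hi)
        scale = amp / base.mean_amp_si
        out.append(replace(
            base,
            mean_period=float(period),
            mean_amp_si=float(amp),
            mean_amp_ap=float(base.mean_amp_ap * scale),
            mean_amp_lr=float(base.mean_amp_lr * scale),
            seed=int(rng.integers(0, 2**31 - 1)),
            label=f"{base.label}-{i:03d}",
        ))
    return out
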