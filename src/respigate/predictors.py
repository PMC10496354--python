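"""Linear motion predictors and baselines.

The prediction model is a pure inner product: from the last ``m`` samples
``x_i`` the positions ``(j-1)*dt`` and ``j*dt`` ahead are forecast as

    yhat_{i,j-1} = x_i' beta_{j-1},     yhat_{i,j} = x_i' beta_j

with no intercept.  Three estimators for ``beta`` are provided:

* ordinary least squares (minimum-norm solution when rank-deficient);
* ridge regression, with the penalty weight chosen by leave-one-out
  cross-validation via the closed-form leverage identity;
* L2-L1 (lasso) regression solved by ADMM with soft-thresholding, with the
  penalty weight chosen by generalized cross-validation (GCV), using the
  number of nonzero coefficients as the effective degrees of freedom.

Baselines: a constant-velocity Kalman filter, a persistence ("dummy")
predictor that repeats the current sample, and an oracle that returns the
true future samples.  The adaptive variant refits the least-squares model
online on an ever-growing buffer after a burn-in period (default 30 s =
150 samples at 5 Hz), admitting each training pair only once its label has
actually been observed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConvergenceWarning, InputError, ParameterError
from .windowing import WindowSet, make_windows

__all__ = [
    "PredictorModel",
    "fit_ols",
    "fit_ridge",
    "admm_lasso",
    "lasso_lambda_max",
    "fit_l2l1",
    "predict_pair",
    "AdaptiveLinearPredictor",
    "ConstantVelocityKF",
    "kalman_predict",
    "dummy_pair",
    "oracle_pair",
    "fit_predictor",
    "DEFAULT_RIDGE_GRID",
    "DEFAULT_LASSO_FRACTIONS",
]

DEFAULT_RIDGE_GRID = np.logspace(-4, 2, 20)
DEFAULT_LASSO_FRACTIONS = np.logspace(-3, np.log10(0.5), 10)


@dataclass
class PredictorModel:
    """Fitted two-horizon linear predictor (coefficients for j-1 and j)."""

    beta_prev: np.ndarray | None
    beta_last: np.ndarray | None
    horizon_j: int = 3
    lam: float = 0.0
    method: str = "ols"
    n_train: int = 0
    m: int = 15
    dt: float = 0.2

    def __post_init__(self) -> None:
        for name in ("beta_prev", "beta_last"):
            b = getattr(self, name)
            if b is not None:
                b = np.asarray(b, dtype=float)
                if b.shape != (self.m,):
                    raise ParameterError(f"{name} must have length m={self.m}")
                setattr(self, name, b)
        if self.lam < 0:
            raise ParameterError("lambda must be >= 0")

    def save(self, path) -> None:
        doc = {
            "method": self.method, "m": self.m, "horizon_j": self.horizon_j,
            "lambda": self.lam, "n_train": self.n_train, "dt": self.dt,
            "beta_prev": None if self.beta_prev is None else self.beta_prev.tolist(),
            "beta_last": None if self.beta_last is None else self.beta_last.tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path) -> "PredictorModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            beta_prev=None if doc["beta_prev"] is None else np.array(doc["beta_prev"]),
            beta_last=None if doc["beta_last"] is None else np.array(doc["beta_last"]),
            horizon_j=doc["horizon_j"], lam=doc["lambda"], method=doc["method"],
            n_train=doc["n_train"], m=doc["m"], dt=doc["dt"],
        )


# ---------------------------------------------------------------------------
# estimators


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.size == 0 or y.size == 0:
        raise InputError("empty design matrix or labels")
    if X.shape[0] != y.size:
        raise InputError("X and y row counts differ")
    return X, y


def fit_ols(X, y) -> np.ndarray:
    """Least-squares coefficients (minimum-norm if rank-deficient)."""
    X, y = _check_xy(X, y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit_ridge(X, y, lambda_grid=DEFAULT_RIDGE_GRID, return_path: bool = False):
    """Ridge coefficients with the penalty chosen by closed-form LOOCV.

    For each candidate ``lam`` the leave-one-out residuals are
    ``e_i / (1 - h_i)`` with ``h_i`` the ridge leverages, computed from one
    SVD of ``X``.  Returns ``(beta, lam)`` at the minimum LOOCV error, plus
    the per-candidate mean-squared LOOCV errors when ``return_path`` is set.
    ``lam = 0`` is allowed and reduces to OLS.
    """
    X, y = _check_xy(X, y)
    grid = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    if grid.size == 0:
        raise ParameterError("lambda grid must be non-empty")
    if np.any(grid < 0):
        raise ParameterError("ridge lambda must be >= 0")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    uty = U.T @ y
    best = (np.inf, None, None)
    path = np.empty(grid.size)
    for k, lam in enumerate(grid):
        shrink = s / (s**2 + lam) if lam > 0 else np.where(s > 0, 1 / s, 0.0)
        beta = Vt.T @ (shrink * uty)
        h = (U**2 * (s * shrink)).sum(axis=1)
        resid = y - X @ beta
        with np.errstate(divide="ignore", invalid="ignore"):
            loo = resid / (1.0 - h)
        err = float(np.mean(loo**2))
        path[k] = err
        if err < best[0]:
            best = (err, beta, float(lam))
    if return_path:
        return best[1], best[2], path
    return best[1], best[2]


def lasso_lambda_max(X, y) -> float:
    """Smallest penalty for which the lasso solution is exactly zero.

    For the objective ``||y - X b||^2 + lam * ||b||_1`` (residual sum of
    squares without a 1/2 factor) the zero-subgradient condition at b = 0 is
    ``lam >= 2 * ||X'y||_inf``.
    """
    X, y = _check_xy(X, y)
    return 2.0 * float(np.max(np.abs(X.T @ y)))


def _soft(v, t):
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def admm_lasso(X, y, lam: float, rho: float | None = None, tol: float = 1e-8,
               max_iter: int = 20000, return_info: bool = False):
    """Lasso coefficients for ``||y - X b||^2 + lam ||b||_1`` via ADMM.

    Standard splitting b/z with scaled dual u: the b-update solves a ridge
    system (re-factorized when the penalty parameter changes), the z-update
    is soft-thresholding at ``lam / (2 rho)``.  The penalty parameter
    starts at ``lam`` and is tuned online by residual balancing, which
    keeps the iteration fast for inputs in physical units.  Stops on the
    combined absolute/relative residual criterion at ``tol``; at the
    iteration limit a :class:`ConvergenceWarning` is issued (no
    exception).  The returned vector is the sparse iterate ``z`` (exact
    zeros).
    """
    X, y = _check_xy(X, y)
    if lam < 0:
        raise ParameterError("lasso lambda must be >= 0")
    if lam == 0:
        return (fit_ols(X, y), {"converged": True, "iterations": 0}) \
            if return_info else fit_ols(X, y)
    m = X.shape[1]
    if lam >= 2.0 * np.max(np.abs(X.T @ y)):
        # zero-subgradient condition: beta = 0 is exactly optimal
        z = np.zeros(m)
        return (z, {"converged": True, "iterations": 0}) if return_info else z
    # objective = 2 * [ (1/2)||y - Xb||^2 + (lam/2)||b||_1 ]
    XtX = X.T @ X
    Xty = X.T @ y
    if rho is None:
        rho = lam  # good starting scale; refined by residual balancing
    chol = np.linalg.cholesky(XtX + rho * np.eye(m))
    b = np.zeros(m)
    z = np.zeros(m)
    u = np.zeros(m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        b = np.linalg.solve(chol.T, np.linalg.solve(chol, Xty + rho * (z - u)))
        z_old = z
        z = _soft(b + u, lam / (2.0 * rho))
        u = u + b - z
        r_norm = np.linalg.norm(b - z)
        s_norm = np.linalg.norm(rho * (z - z_old))
        # combined absolute/relative stopping criterion
        eps_pri = np.sqrt(m) * tol + tol * max(np.linalg.norm(b),
                                               np.linalg.norm(z))
        eps_dual = np.sqrt(m) * tol + tol * np.linalg.norm(rho * u)
        if r_norm < eps_pri and s_norm < eps_dual:
            converged = True
            break
        # residual balancing keeps the iteration fast for any data scale
        if it % 10 == 0 and (r_norm > 10.0 * s_norm
                             or s_norm > 10.0 * r_norm):
            factor = 2.0 if r_norm > 10.0 * s_norm else 0.5
            rho *= factor
            u /= factor
            chol = np.linalg.cholesky(XtX + rho * np.eye(m))
    if not converged:
        warnings.warn(
            f"ADMM lasso stopped at max_iter={max_iter} "
            f"(primal residual {r_norm:.2e})", ConvergenceWarning)
    if return_info:
        return z, {"converged": converged, "iterations": it}
    return z


def fit_l2l1(X, y, lambda_grid=None, rho: float | None = None,
             tol: float = 1e-8, max_iter: int = 20000):
    """L2-L1 (lasso) fit with the penalty chosen by GCV.

    ``GCV(lam) = N * RSS(lam) / (N - df(lam))^2`` with ``df`` the number of
    nonzero coefficients.  Candidates with ``df == N`` (saturated) are
    skipped with a warning.  Default grid: fractions of ``lambda_max``.
    Returns ``(beta, lam)``.
    """
    X, y = _check_xy(X, y)
    n = X.shape[0]
    if lambda_grid is None:
        lambda_grid = DEFAULT_LASSO_FRACTIONS * lasso_lambda_max(X, y)
    grid = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    if grid.size == 0:
        raise ParameterError("lambda grid must be non-empty")
    best = (np.inf, None, None)
    for lam in grid:
        beta = admm_lasso(X, y, lam, rho=rho, tol=tol, max_iter=max_iter)
        df = int(np.count_nonzero(beta))
        if df == n:
            warnings.warn(f"GCV undefined at lambda={lam:g} (saturated fit); "
                          "candidate skipped", ConvergenceWarning)
            continue
        rss = float(np.sum((y - X @ beta) ** 2))
        gcv = n * rss / (n - df) ** 2
        if gcv < best[0]:
            best = (gcv, beta, float(lam))
    if best[1] is None:
        raise ParameterError("all lambda candidates were saturated")
    return best[1], best[2]


def predict_pair(model: PredictorModel, x) -> tuple[float, float]:
    """Forecast ``(yhat_{j-1}, yhat_j)`` from the current m-sample window."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != model.m:
        raise InputError(f"window length {x.size} != m={model.m}")
    if model.method == "dummy":
        return dummy_pair(x)
    if model.method == "kalman":
        j = model.horizon_j
        kf = ConstantVelocityKF(dt=model.dt)
        kf.filter(x)
        return (kf.extrapolate((j - 1) * model.dt), kf.extrapolate(j * model.dt))
    if model.beta_prev is None or model.beta_last is None:
        raise InputError(f"method {model.method!r} has no fitted coefficients")
    return float(x @ model.beta_prev), float(x @ model.beta_last)


def dummy_pair(x) -> tuple[float, float]:
    """Persistence baseline: both horizons equal the current sample."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise InputError("empty window")
    return float(x[-1]), float(x[-1])


def oracle_pair(y_prev: float, y_last: float) -> tuple[float, float]:
    """Oracle baseline: the true future samples themselves."""
    return float(y_prev), float(y_last)


# ---------------------------------------------------------------------------
# adaptive online refitting


class AdaptiveLinearPredictor:
    """Streaming least-squares predictor with burn-in and online refits.

    Samples arrive one at a time.  A training pair for horizon ``h`` enters
    the buffer only once its label has been observed (no lookahead).  The
    model is first fitted when ``burn_in_samples`` samples have arrived
    (default 150 = 30 s at 5 Hz) and refitted every ``refit_every`` newly
    completed pairs thereafter; each refit is a full least-squares solve on
    the whole buffer.  Predictions are emitted only after burn-in.
    """

    def __init__(self, m: int = 15, horizon_j: int = 3,
                 burn_in_samples: int = 150, refit_every: int = 1,
                 dt: float = 0.2):
        if horizon_j < 2:
            raise ParameterError("horizon_j must be >= 2 (two horizons used)")
        if burn_in_samples < m + horizon_j:
            raise ParameterError("burn-in too short to form any training pair")
        self.m = m
        self.horizon_j = horizon_j
        self.burn_in_samples = burn_in_samples
        self.refit_every = refit_every
        self.dt = dt
        self._samples: list[float] = []
        self._times: list[float] = []
        # a pair enters only when its later-horizon label is observed, so both
        # coefficient vectors are always fitted on the same rows
        self._labels_prev: list[float] = []
        self._labels_last: list[float] = []
        self._betas = {horizon_j - 1: None, horizon_j: None}
        self._since_refit = 0
        self._fitted = False

    @property
    def n_samples(self) -> int:
        return len(self._samples)

    @property
    def model(self) -> PredictorModel:
        j = self.horizon_j
        return PredictorModel(self._betas[j - 1], self._betas[j], horizon_j=j,
                              lam=0.0, method="adaptive",
                              n_train=len(self._labels_last), m=self.m, dt=self.dt)

    def _materialize(self) -> int:
        """Append every pair whose labels just became observable; return count."""
        t = len(self._samples)
        j = self.horizon_j
        # pair i (0-based) available once t >= i + m + j
        target = max(0, t - self.m - j + 1)
        new = 0
        while len(self._labels_last) < target:
            i = len(self._labels_last)
            self._labels_prev.append(self._samples[i + self.m + j - 2])
            self._labels_last.append(self._samples[i + self.m + j - 1])
            new += 1
        return new

    def _refit(self) -> None:
        n_pairs = len(self._labels_last)
        if n_pairs == 0:
            return
        arr = np.asarray(self._samples[:n_pairs + self.m - 1])
        X = np.lib.stride_tricks.sliding_window_view(arr, self.m)
        self._betas[self.horizon_j - 1] = fit_ols(X, np.asarray(self._labels_prev))
        self._betas[self.horizon_j] = fit_ols(X, np.asarray(self._labels_last))
        self._fitted = True
        self._since_refit = 0

    def step(self, time: float, value: float):
        """Ingest one sample; return ``(yhat_prev, yhat_last)`` or ``None``."""
        if self._times and time <= self._times[-1]:
            raise InputError("samples must arrive in time order")
        self._times.append(float(time))
        self._samples.append(float(value))
        t = len(self._samples)
        new_pairs = self._materialize()
        self._since_refit += new_pairs
        if t < self.burn_in_samples:
            return None
        if t == self.burn_in_samples:
            self._refit()
            return None  # model fitted; gating starts on the next sample
        if self._since_refit >= self.refit_every:
            self._refit()
        if not self._fitted or self._betas[self.horizon_j] is None:
            return None
        x = np.asarray(self._samples[-self.m:])
        return (float(x @ self._betas[self.horizon_j - 1]),
                float(x @ self._betas[self.horizon_j]))


# ---------------------------------------------------------------------------
# constant-velocity Kalman filter baseline


class ConstantVelocityKF:
    """Scalar constant-velocity Kalman filter (state = position, velocity).

    Process noise follows the continuous white-noise-acceleration model with
    spectral density ``q`` (mm^2/s^3); ``r`` is the measurement noise
    variance (mm^2).  The filter is initialized at the first observation
    with zero velocity and a diffuse velocity variance.
    """

    def __init__(self, dt: float = 0.2, q: float = 1.0, r: float = 0.25,
                 v0_var: float = 100.0):
        if dt <= 0 or q < 0 or r <= 0:
            raise ParameterError("need dt > 0, q >= 0, r > 0")
        self.dt = dt
        self.q = q
        self.r = r
        self.v0_var = v0_var
        self.F = np.array([[1.0, dt], [0.0, 1.0]])
        self.Q = q * np.array([[dt**3 / 3, dt**2 / 2], [dt**2 / 2, dt]])
        self.H = np.array([[1.0, 0.0]])
        self.x = None
        self.P = None

    def filter(self, observations) -> np.ndarray:
        """Run the filter over a segment; return filtered states (n, 2)."""
        z = np.asarray(observations, dtype=float).ravel()
        if z.size < 2:
            raise InputError("need at least 2 samples to filter")
        # prior at the first sample: position = first observation, zero
        # velocity with diffuse variance; updated with every observation
        self.x = np.array([z[0], 0.0])
        self.P = np.diag([self.r, self.v0_var])
        states = np.empty((z.size, 2))
        for k in range(z.size):
            if k > 0:
                self.x = self.F @ self.x
                self.P = self.F @ self.P @ self.F.T + self.Q
            innov = z[k] - self.H @ self.x
            S = self.H @ self.P @ self.H.T + self.r
            K = (self.P @ self.H.T) / S
            self.x = self.x + (K * innov).ravel()
            self.P = (np.eye(2) - K @ self.H) @ self.P
            states[k] = self.x
        return states

    def extrapolate(self, horizon: float) -> float:
        """Predicted position ``horizon`` seconds past the last observation."""
        if self.x is None:
            raise InputError("filter() must run before extrapolate()")
        return float(self.x[0] + self.x[1] * horizon)


def kalman_predict(segment, horizon: float, dt: float = 0.2, q: float = 1.0,
                   r: float = 0.25) -> float:
    """Filter a trace segment and extrapolate ``horizon`` seconds ahead."""
    kf = ConstantVelocityKF(dt=dt, q=q, r=r)
    kf.filter(segment)
    return kf.extrapolate(horizon)


# ---------------------------------------------------------------------------
# batch fitting front-end used by the model layer


def fit_predictor(train: WindowSet, method: str = "ols", horizon_j: int = 3,
                  ridge_grid=DEFAULT_RIDGE_GRID,
                  lasso_fractions=DEFAULT_LASSO_FRACTIONS) -> PredictorModel:
    """Fit ``beta_{j-1}`` and ``beta_j`` on a training WindowSet."""
    if not 2 <= horizon_j <= train.J:
        raise ParameterError(f"horizon_j={horizon_j} needs labels up to J>=2")
    X = train.inputs
    y_prev = train.horizon_labels(horizon_j - 1)
    y_last = train.horizon_labels(horizon_j)
    lam = 0.0
    if method in ("ols", "linear"):
        bp, bl = fit_ols(X, y_prev), fit_ols(X, y_last)
        method = "ols"
    elif method == "ridge":
        bp, lam_p = fit_ridge(X, y_prev, ridge_grid)
        bl, lam_l = fit_ridge(X, y_last, ridge_grid)
        lam = lam_l
    elif method == "l2l1":
        bp, lam_p = fit_l2l1(X, y_prev,
                             np.asarray(lasso_fractions) * lasso_lambda_max(X, y_prev))
        bl, lam_l = fit_l2l1(X, y_last,
                             np.asarray(lasso_fractions) * lasso_lambda_max(X, y_last))
        lam = lam_l
    elif method in ("kalman", "dummy"):
        bp = bl = None
    else:
        raise ParameterError(f"unknown method {method!r}")
    return PredictorModel(bp, bl, horizon_j=horizon_j, lam=lam, method=method,
                          n_train=train.n, m=train.m, dt=train.dt)
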