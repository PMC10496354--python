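# Methods

This note documents the models, numerical choices and known limitations of
`respigate`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Problem setting

A respiratory motion trace sampled at 5 Hz (ΔT = 0.2 s) drives a binary
beam-gating signal: beam on while the trace is below an amplitude threshold
`Th` (the stagnant end-exhale phase), off above it. The delivery chain has
an end-to-end latency, fixed at 0.5 s, so the *ideal* gating signal leads
every true threshold crossing by exactly 0.5 s. The controller must
therefore act on forecasts. With a 0.2 s sampling period the prediction
window can only be 0.4 s (j = 2 samples ahead of the near horizon,
"under-prediction") or 0.6 s (j = 3, "over-prediction"); the mismatch
between either window and the 0.5 s latency is what makes the control
problem interesting.

## Linear predictors

The forecast is a linear map of the last m = 15 samples (≈ 3 s, at least
half a breathing cycle for the cohorts considered), with no intercept: the
window itself carries the baseline, and an intercept would have to be
relearned whenever the baseline drifts. Two coefficient vectors are fitted
independently, one per horizon (j−1 and j), each by minimizing the residual
sum of squares, optionally with an L2 penalty (ridge) or an L1 penalty
(lasso):

* **OLS** — `numpy.linalg.lstsq`; rank-deficient designs get the
  minimum-norm solution, which is deterministic and reproduces any signal
  lying in the span of the window (e.g. sums of a few sinusoids).
* **Ridge** — the penalty weight is selected on a 20-point log-spaced grid
  in [1e−4, 1e2] by leave-one-out cross-validation, computed in closed form
  from one SVD via the leverage identity `e_loo = e / (1 − h)`. λ = 0 is a
  legal candidate and reduces exactly to OLS.
* **L2–L1 (lasso)** — objective `‖y − Xβ‖² + λ‖β‖₁` (no ½ factor on the
  RSS, so the zero-solution boundary is `λ_max = 2‖Xᵀy‖∞`; the solver
  short-circuits to the exact zero vector when λ ≥ λ_max, which the
  subgradient condition makes optimal). Solved by ADMM with
  soft-thresholding at `λ/(2ρ)`. The penalty parameter ρ starts at λ and is
  tuned by residual balancing (×2 / ÷2 every 10 iterations when the primal
  and dual residuals diverge by more than 10×), with the small m×m system
  re-factorized on each change — without this, physical-unit inputs (mm,
  hundreds of rows) make a fixed ρ converge very slowly. Stopping uses the
  combined absolute/relative residual criterion at 1e−8. λ is selected by
  generalized cross-validation, `GCV(λ) = N·RSS/(N − df)²` with df = number
  of nonzero coefficients (the conventional lasso df); saturated candidates
  (df = N) are skipped with a warning.

Baselines: a **constant-velocity Kalman filter** (state = position,
velocity; continuous white-noise-acceleration process noise with spectral
density q = 1 mm²/s³, measurement variance r = 0.25 mm² ≈ (0.5 mm)² for
3 mm pixels with sub-pixel contour tracking; initialized at the first
observation with diffuse velocity variance and updated from the first
sample, matching the state-space convention of statsmodels, which the test
suite uses as an independent reference); a **persistence ("dummy")**
predictor returning the current sample for both horizons; and an **oracle**
returning the true future samples, which bounds achievable performance.

### Adaptive refitting

In adaptive mode the model is first fitted when the burn-in completes
(default 30 s = 150 samples) and refitted after every newly completed
training pair. A pair enters the buffer only when its later-horizon label
has actually been observed — both coefficient vectors are always fitted on
the same rows, and no information from the future of the current decision
time can leak into the fit. Each refit is a full least-squares solve on the
ever-growing buffer; at these problem sizes (≤ a few thousand rows × 15)
this costs well under a millisecond, so no recursive update is needed, and
the streaming trajectory provably equals a batch refit from scratch at
every step (tested to 1e−8). Static mode either uses the first 70% of
windows chronologically (never shuffled: labels are future samples, so a
shuffled split would leak test data into training; the last 20% of the
training pool is reserved as a validation block) or, when
`training_seconds` is given, exactly the pairs fully observed within that
segment — which makes "static with burn-in b" and "adaptive with refits
disabled" literally the same model, a property the tests exploit.

## Crossing-time estimation and gating control

The crossing time is linearly interpolated between the two forecast
horizons; the implementation uses the numerically equivalent standard
two-point form and a tie rule (flat forecast exactly at threshold → the
near horizon time). A toggle is triggered when (A) the threshold is
bracketed between the two forecasts, or (B) the extrapolated crossing falls
within dt_max = 0.1 s beyond the far horizon. dt_max complements the
sampling period: together the A and B windows of successive decisions tile
the timeline, so every crossing of a smoothly forecast trace is seen at
least once and usually twice.

Scheduling and deduplication:

* A toggle is scheduled at `T̂_cross − latency`. When two consecutive
  windows see the same crossing (same direction, estimates within the
  refractory period of 0.5 s), the later, better-informed estimate
  *revises* the pending toggle rather than emitting a second one.
* **Over-prediction (window ≥ latency):** the toggle fires at the estimate
  minus the latency, full stop. Per event, gating error ≡ crossing error —
  the identity the acceptance suite checks to 1e−9 s. The worst-case
  causality shortfall of this idealization is ΔT − dt_max = 0.1 s (a
  crossing first seen by condition B and refined one sample later); the
  published behaviour of this control scheme treats the latency as fully
  compensable in this regime, and so does this implementation.
* **Under-prediction (window < latency):** a toggle can never fire before
  the decision that opened it, so every toggle is structurally late —
  gating errors strictly exceed crossing errors even though the shorter
  horizon predicts the crossing *time* more accurately. This asymmetry is
  why the 0.6 s window is the better operating point when the latency is
  not a multiple of the sampling period.
* **Cold start:** a crossing whose latency-led toggle falls before the
  first decision time of the stream is dropped — the beam simply stays off
  (the conservative state) through it.
* The dummy baseline's flat forecast pairs can never satisfy condition A or
  B, so at pipeline level the dummy controller is crossing-time gating:
  toggles exactly at the true crossing times, hence a gating error of
  exactly the latency (500 ms) at every event — the no-prediction bound.

The threshold defaults to the mean of the SI channel over the burn-in
segment. Gating on the 3D total-motion channel (the per-sample Euclidean
norm of SI/AP/LR displacement from a reference position — series mean by
default, first sample optionally) is available via the channel selector.

## Metrics

MAE, RMSE and R² (observed-mean baseline) score amplitude accuracy on the
far-horizon forecasts. Crossing/gating errors pair predicted events with
reference events by one-to-one nearest match, restricted to same-direction
events within a pairing window of half the estimated breathing period
(median spacing of same-direction reference crossings), so an event can
never be scored against the wrong cycle; unpaired events are counted
separately and penalize gating accuracy through the overlap rather than
inflating the error mean. Gating accuracy is
`100·(1 − symmetric-difference duration / total time)`, computed as an
exact sweep over the union of transition times — no time binning error.
Reference crossings are interpolated between consecutive true samples with
the same tie rule (a sample exactly on the threshold dates the crossing at
that sample, direction from the following movement). Model comparisons use
the two-sided Wilcoxon signed-rank test (scipy), cross-checked in the test
suite against exact sign enumeration at n = 6.

## Synthetic traces

The simulator emulates what the downstream pipeline is sensitive to:
quasi-periodic cycles with a long end-exhale rest (per-cycle profile
`A_k · sin^{2n}(π u)`, exponent 4 by default), per-cycle period and
amplitude drawn from truncated normals (periods > half the mean period,
amplitudes > 0, so no degenerate cycles), linear baseline drift on SI,
i.i.d. Gaussian measurement noise per channel, and AP/LR as amplitude-
scaled (optionally phase-lagged) copies of SI with independent noise,
reflecting the dominance of the superior-inferior axis. Cohort presets
("liver": 21.3 mm mean SI amplitude, 4.6 s mean cycle; "lung": 16.2 mm,
3.4 s) reproduce reported cohort means, and per-patient draws use truncated
normals spanning the reported min–max ranges. Within-trace variability
(period sd 0.25–0.30 s, amplitude sd 8%, noise 0.3 mm, drift 0.5 mm/min)
is chosen to look like free breathing under a 3×3 mm² imaging grid.

What the simulator does *not* produce: coughing, breath-holds, sighs,
pattern drift between breathing modes, or imaging/tracking artefacts.
Passing tests on these traces therefore demonstrate the correctness of the
control and measurement chain and realistic relative orderings of methods,
not clinical performance on patients.

## Problem sizes and determinism

Everything is deterministic given the seeds: the generator uses one
`numpy` PCG64 stream per trace, splits are chronological, and all solvers
are deterministic. Default experiment sizes (120–300 s traces, cohorts of
6–25, a four-point burn-in sweep) run in seconds on one core; the full test
suite takes well under a minute. The acceptance script simulates a 120 s
trace, measures the no-prediction bound over ~45 gating events and the
oracle-driven controller over the same span.

## Known limitations

* The over-prediction scheduling idealization (above) can place a toggle up
  to 0.1 s before the decision that refined it; a hard-real-time
  implementation would be late by that amount on the affected minority of
  events.
* The refractory deduplication (0.5 s, same direction) merges genuine
  double-crossings produced by noise wiggles around the threshold; the
  merged events surface as unpaired ideal transitions and reduced gating
  accuracy rather than as timing errors.
* GCV's df = nonzero-count is an approximation for correlated designs;
  breathing windows are highly collinear, so the lasso route tends to be
  under-penalized relative to ridge — consistent with it trailing OLS and
  ridge on every metric here.
* The Kalman baseline fixes its noise parameters rather than estimating
  them per patient; it is a reference point, not a tuned competitor.
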