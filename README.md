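# respigate

Patient-specific beam-gating control for MRI-guided radiotherapy.

During gated radiotherapy on an MR-linac the beam is only allowed on while
the tumor (or a surrogate organ boundary) sits inside an amplitude "gating
window". The delivery chain — image acquisition, contour tracking, beam
trigger — has an end-to-end latency of about 0.5 s, so a controller that
reacts to the *observed* position toggles the beam half a second late at
every threshold crossing. `respigate` implements the online scheme that
fixes this: a patient-specific linear predictor forecasts the respiratory
trace 0.4 s or 0.6 s ahead, the threshold-crossing time is estimated by
linear interpolation between the two forecast horizons, and the binary
gating signal is toggled early enough to cancel the latency.

Because clinical cine-MR traces are rarely shareable, the package ships a
synthetic breathing-trace simulator (quasi-periodic `sin^{2n}` cycles with
per-cycle period/amplitude variability, baseline drift and measurement
noise, calibrated to reported liver-organ and lung-tumor motion
statistics), so the entire chain is testable end to end.

## The model

From the last m = 15 samples `x_i` (3 s at the 5 Hz imaging rate, ΔT =
0.2 s) two horizons are forecast as pure inner products, with no intercept:

    ŷ_{i,j-1} = x_iᵀ β_{j-1},    ŷ_{i,j} = x_iᵀ β_j,

where j = 2 (0.4 s window, under-prediction) or j = 3 (0.6 s window,
over-prediction relative to the 0.5 s latency). The coefficient vectors are
estimated by

* ordinary least squares,
* ridge regression (λ chosen by closed-form leave-one-out CV), or
* L2–L1 (lasso) regression solved by ADMM (λ chosen by generalized CV),

either once on a 70/30 chronological train/test split, or *adaptively*: fit
on a 30 s burn-in and refit continuously as each new label is observed. A
constant-velocity Kalman filter, a persistence ("dummy") predictor, and an
oracle are available as baselines. The predicted crossing time is

    T̂_cross = (Th − ŷ_{i,j}) / (ŷ_{i,j} − ŷ_{i,j-1}) · ΔT + T_i + j·ΔT,

with threshold `Th` set to the burn-in mean of the SI trace. A beam toggle
is scheduled at `T̂_cross − latency` when the threshold is bracketed between
the two forecasts, or when the extrapolated crossing falls within 0.1 s
beyond the far horizon. Controllers are scored by amplitude metrics (MAE,
RMSE, R²) and by temporal metrics: crossing error, gating error (both ms,
vs the ideal signal that leads every true crossing by the latency) and
gating accuracy (% of therapy time with the correct beam state).

## Worked example

```python
import respigate as rg

params = rg.params_from_preset("liver", duration=120.0, seed=3)
trace = rg.simulate_trace(params)
model = rg.GatingControl(trace, method="ols", window=0.6, adaptive=True)
res = model.fit()
print(res.summary())
```

```
        Gated-Beam Control Results
==============================================
method:            ols (adaptive)
prediction window: 0.6 s (j=3)
channel / m:       si / 15 taps
latency:           0.50 s
threshold:         8.06 mm (burn-in 30 s mean)
lambda:            0
evaluation span:   30.0-120.0 s (39 crossings)
----------------------------------------------
MAE:               1.137 mm
RMSE:              1.528 mm
R^2:               0.9623
crossing error:    55 +/- 41 ms
gating error:      55 +/- 41 ms
gating accuracy:   95.2 %
==============================================
```

Reading the output: after the 30 s burn-in the adaptive least-squares
predictor forecasts the SI trace 0.6 s ahead with 1.5 mm RMSE (sub-pixel at
3 mm resolution); each beam toggle lands on average 55 ms from its ideal,
latency-compensated time; and the generated and ideal gating signals agree
for 95.2% of the 90 s evaluation span. Note the crossing and gating error
columns coincide — with over-prediction the toggle is the crossing estimate
shifted by exactly the latency, so the two errors are identical per event.
A no-prediction controller would be late by the full 500 ms at every
crossing.

The same pipeline is scriptable from the shell:

```
respigate simulate --preset liver -n 21 --seed 0 -o traces/
respigate run --trace traces/liver-000.csv --method ols --window 0.6 --adaptive -o out/
respigate sweep-burnin --preset liver -n 8 --burn-ins 10,20,40,80 -o sweep.csv
respigate compare --dir-a runs_ols/ --dir-b runs_ridge/ --metric gating_accuracy
```

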