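# Liver-organ motion cohort: SI-dominant, slow cycles.
# Cohort means and min-max ranges are the reported movement characteristics
# of liver organs tracked on coronal/sagittal cine-MR at 5 Hz.
label: liver
mean_period: 4.6          # s, cohort mean respiratory cycle
period_range: [2.9, 7.4]  # s, cohort min-max
mean_amp_si: 21.3         # mm, cohort mean SI amplitude
amp_si_range: [5.6, 40.1] # mm, cohort min-max
mean_amp_ap: 7.9          # mm
mean_amp_lr: 9.3          # mm
period_sd: 0.30           # s, within-trace cycle-to-cycle sd
amp_sd_frac: 0.08         # within-trace per-cycle amplitude sd / mean
drift_mm_per_min: 0.5     # mm/min baseline drift
noise_sd: 0.3             # mm additive measurement noise (3x3 mm pixels)
shape_exponent: 4         # sin^{2n} profile, n = 2
duration: 300.0           # s, within the 313-483 s acquisition range
sample_period: 0.2        # s (5 Hz imaging)
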