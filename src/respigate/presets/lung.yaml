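# Lung-tumor motion cohort: faster, shallower cycles than liver.
label: lung
mean_period: 3.4          # s
period_range: [2.4, 5.4]  # s
mean_amp_si: 16.2         # mm
amp_si_range: [3.1, 25.2] # mm
mean_amp_ap: 4.2          # mm
mean_amp_lr: 2.8          # mm
period_sd: 0.25           # s
amp_sd_frac: 0.08
drift_mm_per_min: 0.5     # mm/min
noise_sd: 0.3             # mm
shape_exponent: 4
duration: 300.0           # s
sample_period: 0.2        # s (5 Hz imaging)
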