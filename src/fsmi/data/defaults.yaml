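# Single source of truth for simulator and quantification defaults.
# Binding and noise values are emulation choices: they place the default
# per-antibody detection limits in the 1e3-1e4 cells/mL decade and the best
# tracer dilution near 1/850 (working range 1/800-1/900).
binding:
  s_max: 60000.0          # saturating fluorescence (16-bit scanner scale)
  k_half: 1.0e+5           # half-saturation loading, cells/mL
  tracer_optimum: 1.1764705882352941e-3   # 1/850, dilution fraction
  tracer_log_width: 0.5   # width (decades) of the log-Gaussian tracer response
noise:
  background_mean: 200.0  # additive background fluorescence
  background_sd: 50.0
  sigma: 0.1              # lognormal multiplicative noise scale on true signal
  defect_prob: 0.01       # probability a printed spot is defective
  control_level: 400.0    # expected fluorescence of labelled pre-immune spots
quantify:
  stringency_multiplier: 2.5
  cv_threshold: 0.2
  replicate_aggregator: mean
  clamp_negative: true
simulate:
  checkerboard_concentration: 1.0e+6   # cells/mL, saturating single-antigen assays
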