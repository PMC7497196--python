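# Suite configuration for `matalloc select/run-all --config ...`.
# `defaults` applies to every suite; per-response blocks override it.
defaults:
  scale: 60.0          # chain-length scale-down (1.0 = production lengths)
  n_chains: 2
  loocv_iter: 500
  loocv_burn: 100
  age_forms: ["null", linear, log, quadratic]
proportion:
  reference_masses: [350.0, 450.0, 550.0]
efficiency:
  scale: 120.0         # the slow suite; keep desk runs short
weaning: {}
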