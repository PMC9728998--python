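seed: 7
outdir: vnseeg_demo
simulation:
  n_responders: 5
  n_nonresponders: 5
  channels_per_region: 2   # 10-channel desk-scale montage (F3 F4 T7 T8 C3 C4 P3 P4 O1 O2)
  fs: 256.0
  n_epochs: 20
  leakage: 0.2
analysis:
  scales: [global, regional]
  unit_mode: pooled
  alpha: 0.05
  fit_range: [1, 40]
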