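run:
  seed: 1
  preset: immersed_chamber
  spectrum: ir192
  source: isotropic_point
  xcse_factor: 1024
  shell_r: 0.0
  n_histories: 200000
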