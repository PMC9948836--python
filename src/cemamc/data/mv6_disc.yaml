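run:
  seed: 1
  preset: external_disc
  spectrum: mv6
  source: collimated_point
  xcse_factor: 64
  shell_r: 1.0
  n_histories: 500000
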