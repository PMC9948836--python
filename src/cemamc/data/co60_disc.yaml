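run:
  seed: 1
  preset: external_disc
  spectrum: co60
  source: collimated_point
  xcse_factor: 256
  shell_r: 0.75
  n_histories: 200000
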