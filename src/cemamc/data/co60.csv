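energy_mev,probability
1.1732,0.5
1.3325,0.5
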