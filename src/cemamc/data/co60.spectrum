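co60 fixture spectrum
2, 1.1732, 2
1.1732, 0.5
1.3325, 0.5
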