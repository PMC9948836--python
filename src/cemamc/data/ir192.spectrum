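ir192 fixture spectrum
7, 0.296, 2
0.296, 0.1385804
0.3085, 0.14340898
0.3165, 0.40028972
0.4681, 0.23080637
0.5885, 0.021728634
0.6044, 0.039594399
0.6125, 0.025591502
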