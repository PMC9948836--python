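# mode=histogram lowest=0.25
energy_mev,probability
0.5,0.28626354
0.75,0.16412443
1,0.1117791
1.25,0.082698356
1.5,0.06419243
1.75,0.051380635
2,0.041985319
2.25,0.034800666
2.5,0.029128571
2.75,0.024536875
3,0.020743735
3.25,0.017557497
3.5,0.014843295
3.75,0.012503465
4,0.010465549
4.25,0.0086746527
4.5,0.0070884305
4.75,0.0056736918
5,0.0044040545
5.25,0.0032582842
5.5,0.0022190972
5.75,0.0012722824
6,0.00040604757
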