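percentile,point,ci_lower,ci_upper
0.50,,,
0.75,0.003,0.003,0.003
0.90,0.026,0.026,0.026
0.95,0.108,0.108,0.108
0.975,0.356,0.354,0.357
0.99,1.296,1.290,1.301
0.999,13.10,13.02,13.25
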