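percentile,point,ci_lower,ci_upper
0.50,,,
0.75,0.004,0.004,0.004
0.90,0.057,0.057,0.058
0.95,0.231,0.230,0.232
0.975,0.709,0.706,0.711
0.99,2.352,2.343,2.360
0.999,20.05,19.87,20.23
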