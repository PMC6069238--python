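percentile,point,ci_lower,ci_upper
0.50,1.39,1.35,1.42
0.75,,,
0.90,15.52,15.35,15.70
0.95,,,
0.975,24.07,23.69,24.47
0.99,29.03,28.43,29.66
0.999,40.16,38.39,42.41
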