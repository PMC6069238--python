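percentile,point,ci_lower,ci_upper
0.50,1.67,1.64,1.70
0.75,,,
0.90,10.55,10.44,10.67
0.95,,,
0.975,15.94,15.68,16.19
0.99,19.09,18.70,19.52
0.999,26.07,24.87,27.42
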