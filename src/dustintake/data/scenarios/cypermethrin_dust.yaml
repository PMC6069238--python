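# Cypermethrin via ingestion of indoor dust, 3-6 year old children.
# Note: this row's printed moments (mean 18.33, SD 55.92) and upper
# percentiles (P95 105.79) are mutually inconsistent under a single
# lognormal; scenario_consistency() flags it rather than correcting it.
compound: cypermethrin
route: indoor_dust
adi: 0.02
conversion_factor: 1.0e-3
ingestion_rate:
  kind: moments
  unit: mg/day
  n: 1000
  mean: 26.65
  sd: 36.54
  percentiles:
    0.05: 0.66
    0.25: 4.06
    0.50: 10.80
    0.75: 28.72
    0.95: 100.97
  maximum: 901.96
concentration:
  kind: moments
  unit: ug/g
  n: 52
  mean: 18.33
  sd: 55.92
  lod: 0.031
  percentiles:
    0.05: null
    0.25: 0.11
    0.50: 0.37
    0.75: 0.83
    0.95: 105.79
  maximum: 343.27
body_weight:
  kind: percentiles
  unit: kg
  percentiles:
    0.03: 13.5
    0.15: 15.1
    0.25: 15.8
    0.50: 17.3
    0.75: 19.0
    0.85: 20.1
    0.97: 22.9
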