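# Cypermethrin via ingestion of outdoor yard soil, 3-6 year old children.
compound: cypermethrin
route: outdoor_soil
adi: 0.02
conversion_factor: 1.0e-3
ingestion_rate:
  kind: moments
  unit: mg/day
  n: 1000
  mean: 40.96
  sd: 78.29
  percentiles:
    0.05: 0.15
    0.25: 5.26
    0.50: 15.34
    0.75: 44.85
    0.95: 175.60
  maximum: 1367.37
concentration:
  kind: moments
  unit: ug/g
  n: 57
  mean: 4.29
  sd: 22.32
  lod: 0.031
  percentiles:
    0.05: null
    0.25: null
    0.50: null
    0.75: 0.11
    0.95: 16.47
  maximum: 134.20
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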