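# Chlorpyrifos via ingestion of indoor dust, 3-6 year old children.
# Summary statistics of the published study inputs; null percentile cells
# were printed as below the detection limit.
compound: chlorpyrifos
route: indoor_dust
adi: 0.01              # mg/kg/day (WHO)
conversion_factor: 1.0e-3   # g/mg
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
  mean: 2.32
  sd: 15.41
  lod: 0.025
  percentiles:
    0.05: null
    0.25: 0.08
    0.50: 0.11
    0.75: 0.30
    0.95: 0.91
  maximum: 112.34
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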