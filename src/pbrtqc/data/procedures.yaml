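# Optimized MA procedures for 10 clinical chemistry analytes in a
# small-volume outpatient laboratory: calculation formula, block size or
# weighting factor, truncation limits, control limits (analyte units),
# average daily test volume and total allowable error.
#
# EWMA seeds are the training-population mean; the original training data
# are not distributed, so the packaged seeds are synthetic stand-ins set to
# the midpoint of the control limits.
albumin:
  units: g/L
  formula: simple
  block_size: 10
  control_lower: 40.0
  control_upper: 46.0
  daily_volume: 20
  tea_pct: 10
ast:
  units: U/L
  formula: simple
  block_size: 100
  truncation_upper: 50.0
  control_lower: 17.0
  control_upper: 22.0
  daily_volume: 120
  tea_pct: 20
calcium:
  units: mmol/L
  formula: simple
  block_size: 10
  control_lower: 2.20
  control_upper: 2.61
  daily_volume: 21
  tea_pct: 10
chloride:
  units: mmol/L
  formula: simple
  block_size: 10
  control_lower: 100.0
  control_upper: 107.0
  daily_volume: 23
  tea_pct: 5
cholesterol:
  units: mmol/L
  formula: simple
  block_size: 25
  control_lower: 4.8
  control_upper: 6.4
  daily_volume: 96
  tea_pct: 10
creatinine:
  units: umol/L
  formula: ewma
  weighting_factor: 0.1
  truncation_upper: 150.0
  control_lower: 62.0
  control_upper: 90.0
  ewma_seed: 76.0
  daily_volume: 103
  tea_pct: 15
hdl:
  units: mmol/L
  formula: simple
  block_size: 25
  control_lower: 1.1
  control_upper: 1.6
  daily_volume: 93
  tea_pct: 30
potassium:
  units: mmol/L
  formula: ewma
  weighting_factor: 0.1
  truncation_upper: 6.0
  control_lower: 3.9
  control_upper: 4.8
  ewma_seed: 4.35
  daily_volume: 42
  tea_pct: 18
sodium:
  units: mmol/L
  formula: simple
  block_size: 25
  control_lower: 137.0
  control_upper: 142.0
  daily_volume: 39
  tea_pct: 4
total protein:
  units: g/L
  formula: ewma
  weighting_factor: 0.05
  control_lower: 69.0
  control_upper: 75.0
  ewma_seed: 72.0
  daily_volume: 22
  tea_pct: 10
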