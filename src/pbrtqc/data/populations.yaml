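# Synthetic outpatient population specs, one per analyte.
#
# The real training population is not distributed; these specs are
# synthetic stand-ins anchored to the packaged procedure configs: each
# distribution is centred midway between the analyte's control limits,
# with the CV set so that the stable moving-average range approximately
# spans those limits (for sodium the CV follows the ~1% spread typical of
# an outpatient population). Skewed analytes (enzymes, lipids,
# creatinine) are lognormal; tightly regulated electrolytes and proteins
# are normal. Physiologic bounds truncate the base draw by rejection;
# pathological outliers are injected on top at outlier_rate.
albumin:
  units: g/L
  mean: 43.0
  cv_pct: 5.0
  distribution: normal
  lower_physiologic: 20.0
  upper_physiologic: 55.0
ast:
  units: U/L
  mean: 19.5
  cv_pct: 30.0
  distribution: lognormal
  lower_physiologic: 5.0
  upper_physiologic: 500.0
calcium:
  units: mmol/L
  mean: 2.405
  cv_pct: 6.0
  distribution: normal
  lower_physiologic: 1.5
  upper_physiologic: 3.5
chloride:
  units: mmol/L
  mean: 103.5
  cv_pct: 2.5
  distribution: normal
  lower_physiologic: 85.0
  upper_physiologic: 120.0
cholesterol:
  units: mmol/L
  mean: 5.6
  cv_pct: 17.0
  distribution: lognormal
  lower_physiologic: 2.0
  upper_physiologic: 12.0
creatinine:
  units: umol/L
  mean: 76.0
  cv_pct: 19.0
  distribution: lognormal
  lower_physiologic: 30.0
  upper_physiologic: 1000.0
hdl:
  units: mmol/L
  mean: 1.35
  cv_pct: 22.0
  distribution: lognormal
  lower_physiologic: 0.4
  upper_physiologic: 3.5
potassium:
  units: mmol/L
  mean: 4.35
  cv_pct: 10.0
  distribution: normal
  lower_physiologic: 2.5
  upper_physiologic: 7.5
sodium:
  units: mmol/L
  mean: 139.5
  cv_pct: 1.0
  distribution: normal
  lower_physiologic: 120.0
  upper_physiologic: 160.0
total protein:
  units: g/L
  mean: 72.0
  cv_pct: 6.0
  distribution: normal
  lower_physiologic: 50.0
  upper_physiologic: 95.0
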