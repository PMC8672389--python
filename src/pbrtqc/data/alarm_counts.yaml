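# Example monitoring tallies accompanying the packaged alarm log: number
# of generated MA values and of MA alarms per analyte over six months of
# routine monitoring.
albumin: {n_ma_values: 2538, n_alarms: 1}
ast: {n_ma_values: 15095, n_alarms: 2}
calcium: {n_ma_values: 2667, n_alarms: 0}
chloride: {n_ma_values: 2894, n_alarms: 0}
cholesterol: {n_ma_values: 12147, n_alarms: 3}
creatinine: {n_ma_values: 13008, n_alarms: 2}
hdl: {n_ma_values: 11707, n_alarms: 2}
potassium: {n_ma_values: 5280, n_alarms: 1}
sodium: {n_ma_values: 4891, n_alarms: 5}
total protein: {n_ma_values: 2832, n_alarms: 1}
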