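# Total allowable error per analyte, in percent.
# CLIA values, except where CLIA publishes an absolute concentration:
# for calcium, potassium and sodium the percentage is defined at the
# analyte concentration most critical to medical decision making.
albumin: {tea_pct: 10, source: CLIA}
ast: {tea_pct: 20, source: CLIA}
calcium: {tea_pct: 10, source: Westgard-critical-concentration}
chloride: {tea_pct: 5, source: CLIA}
cholesterol: {tea_pct: 10, source: CLIA}
creatinine: {tea_pct: 15, source: CLIA}
hdl: {tea_pct: 30, source: CLIA}
potassium: {tea_pct: 18, source: Westgard-critical-concentration}
sodium: {tea_pct: 4, source: Westgard-critical-concentration}
total protein: {tea_pct: 10, source: CLIA}
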