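# Example alarm log: 17 MA alarms from six months of routine monitoring of
# 10 clinical chemistry analytes in a small-volume outpatient laboratory,
# with the work-up evidence collected for each and the documented cause and
# actions. Tri-state work-up fields are omitted when the step was not
# performed (review sufficed).
- label: albumin-1
  analyte: albumin
  direction: lower
  extreme_or_consecutive_abnormal: true   # 2 consecutive low results
  patient_history_explains: true          # both patients pregnant
  cause: abnormal_patient_result
  actions: [release_results]
- label: ast-1
  analyte: ast
  direction: upper
  retest_shift: false
  iqc_ok: true
  maintenance_log_clear: true
  cause: no_cause_identified
  actions: [release_results]
- label: ast-2
  analyte: ast
  direction: upper
  extreme_or_consecutive_abnormal: true   # 3 consecutive results near the upper truncation limit
  retest_shift: false
  iqc_ok: true
  maintenance_log_clear: true
  cause: abnormal_patient_result
  actions: [release_results]
- label: cholesterol-1
  analyte: cholesterol
  direction: upper
  extreme_or_consecutive_abnormal: true   # 1 extremely high result
  patient_history_explains: true          # history of extremely high cholesterol
  chronic: true
  cause: abnormal_patient_result
  actions: [release_results, exclude_patient]
- label: cholesterol-2
  analyte: cholesterol
  direction: upper
  extreme_or_consecutive_abnormal: true
  patient_history_explains: true
  chronic: true
  cause: abnormal_patient_result
  actions: [release_results, exclude_patient]
- label: cholesterol-3
  analyte: cholesterol
  direction: upper
  retest_shift: false
  iqc_ok: true
  maintenance_log_clear: true
  cause: no_cause_identified
  actions: [release_results]
- label: creatinine-1
  analyte: creatinine
  direction: upper
  extreme_or_consecutive_abnormal: true   # 1 result near the upper truncation limit
  patient_history_explains: true          # history of elevated creatinine
  chronic: true
  cause: abnormal_patient_result
  actions: [release_results, exclude_patient]
- label: creatinine-2
  analyte: creatinine
  direction: upper
  extreme_or_consecutive_abnormal: true   # 3 results near the upper truncation limit
  retest_shift: false
  iqc_ok: true
  maintenance_log_clear: true
  cause: abnormal_patient_result
  actions: [release_results]
- label: hdl-1
  analyte: hdl
  direction: lower
  extreme_or_consecutive_abnormal: true   # 1 extremely low result
  patient_history_explains: true          # history of extremely low HDL
  chronic: true
  cause: abnormal_patient_result
  actions: [release_results, exclude_patient]
- label: hdl-2
  analyte: hdl
  direction: lower
  retest_shift: false
  iqc_ok: true
  maintenance_log_clear: true
  cause: no_cause_identified
  actions: [release_results]
- label: potassium-1
  analyte: potassium
  direction: lower
  extreme_or_consecutive_abnormal: true   # 1 low result, repeated
  patient_history_explains: true          # repeat on the sample confirmed a genuine low value
  cause: abnormal_patient_result
  actions: [release_results]
- label: sodium-1
  analyte: sodium
  direction: upper
  extreme_or_consecutive_abnormal: true   # 1 high result
  retest_shift: false
  iqc_ok: true
  maintenance_log_clear: true
  cause: abnormal_patient_result
  actions: [release_results]
- label: sodium-2
  analyte: sodium
  direction: upper
  extreme_or_consecutive_abnormal: true   # 1 extremely high result
  preanalytical_problem: dilution         # sample diluted with saline
  cause: preanalytical_sample_problem
  actions: [repeat_on_original_sample, release_results]
- label: sodium-3
  analyte: sodium
  direction: upper
  retest_shift: true
  iqc_ok: true
  iqc_small_shift_sd: 0.5                 # within limits but 0.5 SD upward shift
  maintenance_log_clear: true
  cause: small_analytical_shift
  actions: [recalibrate_and_retest_day]
- label: sodium-4
  analyte: sodium
  direction: lower
  retest_shift: false
  iqc_ok: true
  maintenance_log_clear: true
  cause: no_cause_identified
  actions: [release_results]
- label: sodium-5
  analyte: sodium
  direction: lower
  retest_shift: true
  iqc_ok: true
  iqc_small_shift_sd: -0.4                # within limits but 0.4 SD downward shift
  maintenance_log_clear: true
  cause: small_analytical_shift
  actions: [recalibrate_and_retest_day]
- label: total protein-1
  analyte: total protein
  direction: upper
  extreme_or_consecutive_abnormal: true   # 1 extremely high result
  preanalytical_problem: lipemia          # lipemic serum
  cause: preanalytical_sample_problem
  actions: [request_new_sample, release_results]
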