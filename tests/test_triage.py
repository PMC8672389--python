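"""Alarm work-up algorithm, retest/IQC rules, and monitoring reports."""

import pytest

from pbrtqc.triage import (
    Action,
    AlarmContext,
    Cause,
    PreanalyticalProblem,
    WorkupIncompleteError,
    alarm_rate_report,
    analytical_shift_detected,
    cause_summary_report,
    classify_alarm,
    iqc_check,
    load_alarm_contexts,
)


class TestClassifyAlarm:
    def test_extreme_result_explained_by_chronic_history(self):
        # e.g. an upper cholesterol alarm from one extremely high result in
        # a patient with known extreme cholesterol
        ctx = AlarmContext(
            extreme_or_consecutive_abnormal=True,
            patient_history_explains=True,
            chronic=True,
        )
        finding = classify_alarm(ctx)
        assert finding.cause is Cause.abnormal_patient_result
        assert finding.actions == {Action.release_results, Action.exclude_patient}

    def test_retest_shift_with_subtle_iqc_drift(self):
        # review unremarkable, retest shows a shift, IQC within limits but
        # drifted 0.5 SD upward
        ctx = AlarmContext(
            retest_shift=True, iqc_ok=True, iqc_small_shift_sd=0.5,
            maintenance_log_clear=True,
        )
        finding = classify_alarm(ctx)
        assert finding.cause is Cause.small_analytical_shift
        assert finding.actions == {Action.recalibrate_and_retest_day}

    def test_lipemic_sample_is_preanalytical(self):
        ctx = AlarmContext(
            extreme_or_consecutive_abnormal=True,
            preanalytical_problem=PreanalyticalProblem.lipemia,
        )
        finding = classify_alarm(ctx)
        assert finding.cause is Cause.preanalytical_sample_problem
        assert finding.actions == {Action.request_new_sample, Action.release_results}

    def test_saline_dilution_repeats_on_original_sample(self):
        ctx = AlarmContext(preanalytical_problem=PreanalyticalProblem.dilution)
        finding = classify_alarm(ctx)
        assert finding.cause is Cause.preanalytical_sample_problem
        assert Action.repeat_on_original_sample in finding.actions

    def test_all_steps_clear_means_no_cause(self):
        ctx = AlarmContext(retest_shift=False, iqc_ok=True, maintenance_log_clear=True)
        finding = classify_alarm(ctx)
        assert finding.cause is Cause.no_cause_identified
        assert finding.actions == {Action.release_results}

    def test_missing_retest_step_raises_naming_the_step(self):
        with pytest.raises(WorkupIncompleteError, match="retest"):
            classify_alarm(AlarmContext())

    def test_missing_iqc_step_raises_naming_the_step(self):
        with pytest.raises(WorkupIncompleteError, match="IQC"):
            classify_alarm(AlarmContext(retest_shift=False))

    def test_pure_function_identical_contexts_identical_findings(self):
        ctx = AlarmContext(retest_shift=False, iqc_ok=True, maintenance_log_clear=True)
        assert classify_alarm(ctx) == classify_alarm(ctx)


class TestAlarmLogFixtures:
    def test_every_logged_alarm_reproduces_its_documented_cause_and_actions(self):
        entries = load_alarm_contexts()
        assert len(entries) == 17
        for entry in entries:
            finding = classify_alarm(entry["context"])
            assert finding.cause is entry["cause"], entry["label"]
            assert finding.actions == entry["actions"], entry["label"]

    def test_cause_category_totals(self):
        entries = load_alarm_contexts()
        findings = [classify_alarm(e["context"]) for e in entries]
        by_cause = {
            cause: sum(1 for f in findings if f.cause is cause) for cause in Cause
        }
        assert by_cause == {
            Cause.abnormal_patient_result: 9,
            Cause.preanalytical_sample_problem: 2,
            Cause.small_analytical_shift: 2,
            Cause.no_cause_identified: 4,
        }


class TestRetestRule:
    def test_one_large_difference_triggers(self):
        pairs = [(10.0, 15.0), (10.0, 10.1), (10.0, 9.9)]
        assert analytical_shift_detected(pairs, analytical_sd=2.0)

    def test_exactly_two_sd_is_not_a_shift(self):
        pairs = [(10.0, 14.0)] * 3
        assert not analytical_shift_detected(pairs, analytical_sd=2.0)

    def test_identical_results_no_shift(self):
        assert not analytical_shift_detected([(5.0, 5.0)] * 3, 1.0)

    def test_requires_exactly_three_pairs(self):
        with pytest.raises(ValueError, match="3"):
            analytical_shift_detected([(1.0, 1.0)] * 2, 1.0)


class TestIqcCheck:
    def test_values_at_target_pass_with_zero_shift(self):
        ok, shifts = iqc_check([5.0, 10.0, 20.0], [5.0, 10.0, 20.0], [0.2, 0.4, 0.8])
        assert ok and shifts == [0.0, 0.0, 0.0]

    def test_one_level_beyond_two_sd_fails(self):
        ok, _ = iqc_check([5.5, 10.0, 20.0], [5.0, 10.0, 20.0], [0.2, 0.4, 0.8])
        assert not ok

    def test_half_sd_drift_passes_but_is_reported(self):
        ok, shifts = iqc_check(
            [5.1, 10.2, 20.4], [5.0, 10.0, 20.0], [0.2, 0.4, 0.8]
        )
        assert ok
        assert shifts == pytest.approx([0.5, 0.5, 0.5])

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            iqc_check([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 0.0, 1.0])


class TestAlarmRateReport:
    def test_rates_match_counts(self):
        frame = alarm_rate_report({"sodium": (4891, 5), "calcium": (2667, 0)})
        by_analyte = frame.set_index("analyte")
        assert by_analyte.loc["sodium", "rate_pct"] == 0.102
        assert by_analyte.loc["calcium", "rate_pct"] == 0.0

    def test_totals_row_sums_counts(self):
        frame = alarm_rate_report({"a": (100, 1), "b": (300, 2)})
        total = frame[frame["analyte"] == "total"].iloc[0]
        assert total["n_ma_values"] == 400 and total["n_alarms"] == 3
        assert total["rate_pct"] == 0.75

    def test_alarms_without_ma_values_is_an_error(self):
        with pytest.raises(ValueError):
            alarm_rate_report({"x": (0, 1)})

    def test_zero_over_zero_reports_zero_with_note(self):
        frame = alarm_rate_report({"x": (0, 0)})
        row = frame[frame["analyte"] == "x"].iloc[0]
        assert row["rate_pct"] == 0.0 and row["note"] == "no MA values"


class TestCauseSummaryReport:
    def _findings(self, counts):
        out = []
        for cause, k in counts.items():
            out.extend([  # actions irrelevant to the summary
                classify_alarm(_ctx_for(cause)) for _ in range(k)
            ])
        return out

    def test_percentages_round_half_up(self):
        findings = self._findings(
            {
                Cause.abnormal_patient_result: 9,
                Cause.preanalytical_sample_problem: 2,
                Cause.small_analytical_shift: 2,
                Cause.no_cause_identified: 4,
            }
        )
        frame = cause_summary_report(findings).set_index("cause")
        assert frame.loc["abnormal_patient_result", "percent"] == 53
        assert frame.loc["preanalytical_sample_problem", "percent"] == 12
        assert frame.loc["small_analytical_shift", "percent"] == 12
        assert frame.loc["no_cause_identified", "percent"] == 24  # 4/17 = 23.5

    def test_flags_when_rounded_percentages_do_not_sum_to_100(self):
        findings = self._findings(
            {
                Cause.abnormal_patient_result: 9,
                Cause.preanalytical_sample_problem: 2,
                Cause.small_analytical_shift: 2,
                Cause.no_cause_identified: 4,
            }
        )
        frame = cause_summary_report(findings)
        assert frame.attrs["percent_sum"] == 101
        assert not frame.attrs["percent_sum_is_100"]

    def test_single_cause_is_one_hundred_percent(self):
        findings = self._findings({Cause.no_cause_identified: 3})
        frame = cause_summary_report(findings).set_index("cause")
        assert frame.loc["no_cause_identified", "percent"] == 100
        assert frame["count"].sum() == 3

    def test_empty_findings_rejected(self):
        with pytest.raises(ValueError):
            cause_summary_report([])


def _ctx_for(cause):
    """A minimal context classifying to the requested cause."""
    if cause is Cause.abnormal_patient_result:
        return AlarmContext(
            extreme_or_consecutive_abnormal=True, patient_history_explains=True
        )
    if cause is Cause.preanalytical_sample_problem:
        return AlarmContext(preanalytical_problem=PreanalyticalProblem.lipemia)
    if cause is Cause.small_analytical_shift:
        return AlarmContext(retest_shift=True)
    return AlarmContext(retest_shift=False, iqc_ok=True, maintenance_log_clear=True)
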