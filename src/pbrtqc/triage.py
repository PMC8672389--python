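"""Alarm evaluation: work-up algorithm, retest rule, IQC check, reports.

When an MA alarm fires, the laboratory works it up in a fixed order:

1. **Review of patient results** around the alarm. If an extreme or
   consecutively abnormal contributing result is explained by the
   patient's history or clinical condition, the alarm is attributed to an
   abnormal patient result; a chronically pathological patient can be
   excluded from future MA calculations.
2. **Pre-analytical inspection** of the flagged samples (saline dilution,
   lipemia, haemolysis, ...).
3. **Retest rule**: re-analysis of 3 patient samples from a stable period
   (a prior working day with no alarm for the analyte); an analytical
   shift is declared when at least one original/retest difference exceeds
   2 analytical standard deviations.
4. **IQC and maintenance log**: 3 control levels under a 1:2s rule plus a
   review of the analyser's malfunction and maintenance log.

If review flagged abnormal contributing results but steps 2-4 exonerate
the analytical process, the cause is still the abnormal patient result;
if nothing at any step explains the alarm, no cause is identified and the
results are released.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "Cause",
    "Action",
    "PreanalyticalProblem",
    "AlarmContext",
    "AlarmFinding",
    "classify_alarm",
    "analytical_shift_detected",
    "iqc_check",
    "alarm_rate_report",
    "cause_summary_report",
    "load_alarm_contexts",
    "WorkupIncompleteError",
]


class Cause(str, enum.Enum):
    """Groups of detected causes of MA alarms."""

    abnormal_patient_result = "abnormal_patient_result"
    preanalytical_sample_problem = "preanalytical_sample_problem"
    small_analytical_shift = "small_analytical_shift"
    no_cause_identified = "no_cause_identified"


class Action(str, enum.Enum):
    """Actions taken on patient results after an alarm work-up."""

    release_results = "release_results"
    exclude_patient = "exclude_patient"
    request_new_sample = "request_new_sample"
    repeat_on_original_sample = "repeat_on_original_sample"
    recalibrate_and_retest_day = "recalibrate_and_retest_day"


class PreanalyticalProblem(str, enum.Enum):
    none = "none"
    dilution = "dilution"
    lipemia = "lipemia"
    hemolysis = "hemolysis"
    other = "other"


class WorkupIncompleteError(Exception):
    """The decision path requires a work-up step that was not performed."""


@dataclass(frozen=True)
class AlarmContext:
    """Evidence collected while working up one MA alarm.

    Tri-state fields use ``None`` for "step not performed". The evidence
    is consumed strictly in the order of the work-up algorithm; a step is
    only required if no earlier step already explained the alarm.
    """

    analyte: str = ""
    direction: str = ""
    extreme_or_consecutive_abnormal: bool = False
    patient_history_explains: bool = False
    chronic: bool = False
    preanalytical_problem: PreanalyticalProblem = PreanalyticalProblem.none
    retest_shift: Optional[bool] = None
    iqc_ok: Optional[bool] = None
    iqc_small_shift_sd: Optional[float] = None
    maintenance_log_clear: Optional[bool] = None


@dataclass(frozen=True)
class AlarmFinding:
    """Outcome of an alarm work-up: cause category and recommended actions."""

    cause: Cause
    actions: frozenset  # of Action


def classify_alarm(ctx: AlarmContext) -> AlarmFinding:
    """Apply the alarm-evaluation decision algorithm to collected evidence.

    Deterministic and pure: identical contexts yield identical findings.
    Raises :class:`WorkupIncompleteError` when the path reaches a step
    whose evidence is missing.
    """
    # step 1: review of patient results
    if ctx.extreme_or_consecutive_abnormal and ctx.patient_history_explains:
        actions = {Action.release_results}
        if ctx.chronic:
            actions.add(Action.exclude_patient)
        return AlarmFinding(Cause.abnormal_patient_result, frozenset(actions))

    # step 2: pre-analytical inspection
    if ctx.preanalytical_problem is not PreanalyticalProblem.none:
        repeat = (
            Action.repeat_on_original_sample
            if ctx.preanalytical_problem is PreanalyticalProblem.dilution
            else Action.request_new_sample
        )
        return AlarmFinding(
            Cause.preanalytical_sample_problem,
            frozenset({repeat, Action.release_results}),
        )

    # step 3: retest of 3 stable-period samples
    if ctx.retest_shift is None:
        raise WorkupIncompleteError(
            "retest of 3 stable-period samples not performed"
        )
    if ctx.retest_shift:
        return AlarmFinding(
            Cause.small_analytical_shift,
            frozenset({Action.recalibrate_and_retest_day}),
        )

    # step 4: IQC and maintenance log
    if ctx.iqc_ok is None:
        raise WorkupIncompleteError("IQC check (3 levels, 1:2s) not performed")
    if ctx.maintenance_log_clear is None:
        raise WorkupIncompleteError("maintenance/error log review not performed")
    if not ctx.iqc_ok:
        # an out-of-limits IQC after a negative retest still points at the
        # analytical process
        return AlarmFinding(
            Cause.small_analytical_shift,
            frozenset({Action.recalibrate_and_retest_day}),
        )
    if ctx.extreme_or_consecutive_abnormal:
        # review flagged abnormal contributors and every later step
        # exonerated the process: the patient results explain the alarm
        return AlarmFinding(
            Cause.abnormal_patient_result, frozenset({Action.release_results})
        )
    return AlarmFinding(Cause.no_cause_identified, frozenset({Action.release_results}))


def analytical_shift_detected(
    pairs: Sequence[tuple[float, float]], analytical_sd: float
) -> bool:
    """Retest rule on 3 (original, retest) stable-period sample pairs.

    True iff at least one absolute difference is *strictly* greater than
    2 analytical standard deviations.
    """
    if len(pairs) != 3:
        raise ValueError(f"exactly 3 retest pairs required, got {len(pairs)}")
    if analytical_sd <= 0:
        raise ValueError("analytical_sd must be > 0")
    return any(abs(orig - retest) > 2.0 * analytical_sd for orig, retest in pairs)


def iqc_check(
    control_values: Sequence[float],
    targets: Sequence[float],
    sds: Sequence[float],
) -> tuple[bool, list[float]]:
    """Three-level IQC under the 1:2s rule.

    Returns ``(ok, shifts)`` where ``ok`` is true iff every control value
    is within 2 SD of its target, and ``shifts`` is the signed deviation
    of each level in SD units — small but consistent shifts (e.g. all
    levels +0.5 SD) are evidence during triage even when the rule passes.
    """
    if not len(control_values) == len(targets) == len(sds) == 3:
        raise ValueError("three (value, target, sd) triples required")
    if any(sd <= 0 for sd in sds):
        raise ValueError("control SDs must be > 0")
    shifts = [(v - t) / sd for v, t, sd in zip(control_values, targets, sds)]
    ok = all(abs(s) <= 2.0 for s in shifts)
    return ok, shifts


def _round_half_up(x: float, digits: int = 0) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def alarm_rate_report(counts: dict) -> pd.DataFrame:
    """Per-analyte alarm rates plus an overall totals row.

    ``counts`` maps analyte name to ``(n_ma_values, n_alarms)``. The rate
    is ``100 * alarms / ma_values`` rounded half-up to 3 decimals. A
    degenerate analyte with no MA values is reported with rate 0 and a
    note; alarms without MA values are a contract violation.
    """
    rows = []
    total_values = total_alarms = 0
    for analyte, (n_values, n_alarms) in counts.items():
        if n_values < 0 or n_alarms < 0:
            raise ValueError("counts must be >= 0")
        if n_values == 0 and n_alarms > 0:
            raise ValueError(f"{analyte}: alarms reported without MA values")
        note = "no MA values" if n_values == 0 else ""
        rate = _round_half_up(100.0 * n_alarms / n_values, 3) if n_values else 0.0
        rows.append(
            {
                "analyte": analyte,
                "n_ma_values": n_values,
                "n_alarms": n_alarms,
                "rate_pct": rate,
                "note": note,
            }
        )
        total_values += n_values
        total_alarms += n_alarms
    total_rate = (
        _round_half_up(100.0 * total_alarms / total_values, 3) if total_values else 0.0
    )
    rows.append(
        {
            "analyte": "total",
            "n_ma_values": total_values,
            "n_alarms": total_alarms,
            "rate_pct": total_rate,
            "note": "" if total_values else "no MA values",
        }
    )
    return pd.DataFrame(rows)


def cause_summary_report(findings: Sequence[AlarmFinding]) -> pd.DataFrame:
    """Counts and percentages per cause category.

    Percentages are rounded half-up to integers; when the rounded column
    does not sum to 100 the report flags it rather than forcing the sum.
    """
    if not findings:
        raise ValueError("no findings to summarize")
    total = len(findings)
    rows = []
    for cause in Cause:
        count = sum(1 for f in findings if f.cause is cause)
        rows.append(
            {
                "cause": cause.value,
                "count": count,
                "percent": _round_half_up(100.0 * count / total),
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["percent_sum"] = int(frame["percent"].sum())
    frame.attrs["percent_sum_is_100"] = frame.attrs["percent_sum"] == 100
    return frame


def parse_context(raw: dict) -> AlarmContext:
    return AlarmContext(
        analyte=raw.get("analyte", ""),
        direction=raw.get("direction", ""),
        extreme_or_consecutive_abnormal=raw.get(
            "extreme_or_consecutive_abnormal", False
        ),
        patient_history_explains=raw.get("patient_history_explains", False),
        chronic=raw.get("chronic", False),
        preanalytical_problem=PreanalyticalProblem(
            raw.get("preanalytical_problem", "none")
        ),
        retest_shift=raw.get("retest_shift"),
        iqc_ok=raw.get("iqc_ok"),
        iqc_small_shift_sd=raw.get("iqc_small_shift_sd"),
        maintenance_log_clear=raw.get("maintenance_log_clear"),
    )


def load_alarm_contexts(path: Optional[str] = None) -> list[dict]:
    """Load the packaged example alarm log (17 worked-up alarms).

    Each entry holds the alarm label, the evidence as an
    :class:`AlarmContext`, and the documented cause and actions for that
    alarm. The log doubles as a regression fixture for the classifier.
    """
    if path is None:
        text = resources.files("pbrtqc.data").joinpath("alarm_log.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    entries = []
    for raw in yaml.safe_load(text):
        entries.append(
            {
                "label": raw["label"],
                "context": parse_context(raw),
                "cause": Cause(raw["cause"]),
                "actions": frozenset(Action(a) for a in raw["actions"]),
            }
        )
    return entries
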