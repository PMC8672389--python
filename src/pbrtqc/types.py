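"""Domain types for moving-average patient-based quality control.

Configuration objects (:class:`AnalyteConfig`, :class:`MAProcedure`) are
pydantic models so they validate on construction and round-trip through
JSON/YAML configs. Stream records (:class:`PatientResult`, :class:`MAPoint`)
are frozen dataclasses: they sit on the hot path of the streaming engines.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator


class Formula(str, enum.Enum):
    """Moving-average calculation formula."""

    simple = "simple"
    ewma = "ewma"


class AlarmDirection(str, enum.Enum):
    """Side of the control interval an MA value violated."""

    none = "none"
    lower = "lower"
    upper = "upper"


class AnalyteConfig(BaseModel):
    """Per-analyte analytical performance configuration.

    Parameters
    ----------
    analyte_name, units:
        Test identity, e.g. ``sodium`` in ``mmol/L``.
    tea_pct:
        Total allowable error in percent (CLIA-based, or a critical-
        concentration percentage where CLIA publishes an absolute value).
    min_tea_pct:
        Optional biological-variation minimum allowable error in percent;
        may be attainable in one direction only (sign carried by the user).
    daily_volume:
        Average number of tests per working day — the budget within which a
        TEa-sized bias must be detected for a procedure to be acceptable.
    cvi, cvg:
        Intra- and inter-individual biological coefficients of variation in
        percent, used by the minimum-TEa formula.
    """

    model_config = ConfigDict(frozen=True)

    analyte_name: str
    units: str = ""
    tea_pct: float
    min_tea_pct: Optional[float] = None
    daily_volume: int = 1
    cvi: Optional[float] = None
    cvg: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "AnalyteConfig":
        if self.tea_pct <= 0:
            raise ValueError("tea_pct must be > 0")
        if self.daily_volume < 1:
            raise ValueError("daily_volume must be >= 1")
        for name in ("cvi", "cvg"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        return self


class MAProcedure(BaseModel):
    """Full parameterization of one moving-average control procedure.

    Exactly one of ``block_size`` (simple MA) or ``weighting_factor``
    (EWMA) must be set, matching ``formula``. Control limits are in the
    analyte's concentration units and are typically the min/max of the MA
    observed on a stable training period. ``ewma_seed`` is the starting
    value z(0) of the EWMA recursion — the mean of the training population.
    """

    model_config = ConfigDict(frozen=True)

    analyte_name: str
    formula: Formula
    block_size: Optional[int] = None
    weighting_factor: Optional[float] = None
    truncation_lower: Optional[float] = None
    truncation_upper: Optional[float] = None
    control_lower: float
    control_upper: float
    ewma_seed: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "MAProcedure":
        if self.formula is Formula.simple:
            if self.block_size is None or self.weighting_factor is not None:
                raise ValueError("simple MA requires block_size and no weighting_factor")
            if self.block_size < 1:
                raise ValueError("block_size must be >= 1")
        else:
            if self.weighting_factor is None or self.block_size is not None:
                raise ValueError("EWMA requires weighting_factor and no block_size")
            if not 0 < self.weighting_factor <= 1:
                raise ValueError("weighting_factor must be in (0, 1]")
            if self.ewma_seed is None:
                raise ValueError("EWMA requires ewma_seed (training-population mean)")
        if (
            self.truncation_lower is not None
            and self.truncation_upper is not None
            and not self.truncation_lower < self.truncation_upper
        ):
            raise ValueError("truncation_lower must be < truncation_upper")
        if not self.control_lower < self.control_upper:
            raise ValueError("control_lower must be < control_upper")
        return self

    def with_limits(self, lower: float, upper: float) -> "MAProcedure":
        """Return a copy with new control limits."""
        return self.model_copy(update={"control_lower": lower, "control_upper": upper})


@dataclass(frozen=True)
class PatientResult:
    """One analyte measurement received from the analyser.

    ``hil_flags`` carries the haemolysis/icterus/lipemia interference
    indices transmitted with the result (subset of ``{"H", "I", "L"}``);
    flagged results still enter the MA calculation — interference is an
    alarm *cause* handled downstream during triage, not an inclusion rule.
    ``is_control`` marks internal/external QC material, which never enters
    patient-based calculations.
    """

    sample_id: str
    patient_id: str
    timestamp: datetime
    analyte_name: str
    value: float
    hil_flags: frozenset = frozenset()
    is_control: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite result value for sample {self.sample_id!r}")

    def with_value(self, value: float) -> "PatientResult":
        return PatientResult(
            sample_id=self.sample_id,
            patient_id=self.patient_id,
            timestamp=self.timestamp,
            analyte_name=self.analyte_name,
            value=value,
            hil_flags=self.hil_flags,
            is_control=self.is_control,
        )


@dataclass(frozen=True)
class MAPoint:
    """One computed moving-average value, tied to the result that triggered it.

    ``index`` counts included results (0-based). ``warmup`` marks simple-MA
    points computed before the rolling window first held ``block_size``
    values; warm-up points are never alarm-eligible.
    """

    index: int
    source_result: PatientResult
    ma_value: float
    alarm: AlarmDirection = AlarmDirection.none
    warmup: bool = False

    @property
    def is_alarm(self) -> bool:
        return self.alarm is not AlarmDirection.none


@dataclass
class ExclusionRegistry:
    """Patients excluded from future MA calculations for a given analyte.

    Used when triage identifies a chronic pathological value (e.g. a
    patient with persistently extreme cholesterol) whose every visit would
    otherwise re-trigger alarms. Membership is idempotent.
    """

    _entries: dict = field(default_factory=dict)

    def exclude(self, patient_id: str, analyte_name: str, reason: str = "") -> None:
        self._entries.setdefault((patient_id, analyte_name.lower()), reason)

    def is_excluded(self, patient_id: str, analyte_name: str) -> bool:
        return (patient_id, analyte_name.lower()) in self._entries

    def reason(self, patient_id: str, analyte_name: str) -> Optional[str]:
        return self._entries.get((patient_id, analyte_name.lower()))

    def __len__(self) -> int:
        return len(self._entries)
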