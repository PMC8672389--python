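"""Streaming moving-average engines and result-inclusion rules.

The laboratory information system recalculates the moving average at every
new patient result and raises an alarm whenever the MA value leaves its
control interval. Two calculators are provided:

* simple MA — the arithmetic mean of the last ``n`` included results
  (rolling block), z(t) = x(t)/n + x(t-1)/n + ... + x(t-n+1)/n;
* EWMA — z(t) = lambda * x(t) + (1 - lambda) * z(t-1), seeded with the
  training-population mean.

A result enters the calculation only if it is a patient sample (not QC
material), its patient is not registered as excluded for the analyte, and
its value lies inside the procedure's truncation limits. Exclusion is
strictly "outside": a value exactly on a truncation limit is included.
Alarms are likewise strict: an MA value exactly on a control limit does not
alarm, since the limits are the attained min/max of stable training data.
"""

from __future__ import annotations

import math
from collections import deque
from typing import Iterable, Optional, Sequence

from pbrtqc.types import (
    AlarmDirection,
    ExclusionRegistry,
    Formula,
    MAPoint,
    MAProcedure,
    PatientResult,
)

__all__ = [
    "is_includable",
    "simple_ma_step",
    "ewma_step",
    "SimpleMAEngine",
    "EwmaEngine",
    "make_engine",
    "process_stream",
]


def is_includable(
    result: PatientResult,
    proc: MAProcedure,
    registry: Optional[ExclusionRegistry] = None,
) -> bool:
    """Decide whether a result enters the MA calculation.

    Control-sample measurements, results from excluded patients, and values
    outside the truncation limits are rejected; a missing truncation bound
    is unbounded. Never mutates any state.
    """
    if result.analyte_name.lower() != proc.analyte_name.lower():
        raise ValueError(
            f"analyte mismatch: result is {result.analyte_name!r}, "
            f"procedure is for {proc.analyte_name!r}"
        )
    if result.is_control:
        return False
    if registry is not None and registry.is_excluded(result.patient_id, result.analyte_name):
        return False
    if proc.truncation_lower is not None and result.value < proc.truncation_lower:
        return False
    if proc.truncation_upper is not None and result.value > proc.truncation_upper:
        return False
    return True


def simple_ma_step(
    window_state: Sequence[float], x: float, n: int
) -> tuple[deque, float, bool]:
    """Advance a simple rolling mean by one included value.

    Returns ``(new_window, ma_value, warmup)`` where ``ma_value`` is the
    arithmetic mean of the last ``min(k, n)`` included values (``k`` values
    seen so far) and ``warmup`` is true while ``k < n``.
    """
    if n < 1:
        raise ValueError("block size must be >= 1")
    if not math.isfinite(x):
        raise ValueError("non-finite value rejected")
    window = deque(window_state, maxlen=n)
    window.append(x)
    return window, sum(window) / len(window), len(window) < n


def ewma_step(z_prev: float, x: float, lam: float) -> float:
    """One step of the EWMA recursion z(t) = lam*x(t) + (1-lam)*z(t-1)."""
    if not 0 < lam <= 1:
        raise ValueError("weighting factor must be in (0, 1]")
    if not math.isfinite(z_prev):
        raise ValueError("non-finite previous EWMA value")
    if not math.isfinite(x):
        raise ValueError("non-finite value rejected")
    return lam * x + (1.0 - lam) * z_prev


class SimpleMAEngine:
    """Stateful rolling-mean calculator (block size ``n``)."""

    def __init__(self, n: int):
        if n < 1:
            raise ValueError("block size must be >= 1")
        self.n = n
        self._window: deque = deque(maxlen=n)
        self._sum = 0.0
        self._count = 0

    def update(self, x: float) -> tuple[float, bool]:
        """Feed one included value; return ``(ma_value, warmup)``.

        Maintains a running sum for O(1) updates; the sum is refreshed from
        the window contents every few hundred updates to keep accumulated
        rounding drift far below 1e-12 relative.
        """
        if not math.isfinite(x):
            raise ValueError("non-finite value rejected")
        if len(self._window) == self.n:
            self._sum -= self._window[0]
        self._window.append(x)
        self._sum += x
        self._count += 1
        if self._count % 256 == 0:
            self._sum = math.fsum(self._window)
        k = len(self._window)
        return self._sum / k, k < self.n

    @property
    def state(self) -> tuple[float, ...]:
        return tuple(self._window)


class EwmaEngine:
    """Stateful exponentially-weighted moving-average calculator."""

    def __init__(self, lam: float, seed: float):
        if not 0 < lam <= 1:
            raise ValueError("weighting factor must be in (0, 1]")
        if not math.isfinite(seed):
            raise ValueError("non-finite EWMA seed")
        self.lam = lam
        self.z = seed

    def update(self, x: float) -> tuple[float, bool]:
        self.z = ewma_step(self.z, x, self.lam)
        return self.z, False

    @property
    def state(self) -> float:
        return self.z


def make_engine(proc: MAProcedure):
    """Build the streaming calculator matching a procedure's formula."""
    if proc.formula is Formula.simple:
        return SimpleMAEngine(proc.block_size)
    return EwmaEngine(proc.weighting_factor, proc.ewma_seed)


def _alarm_direction(ma_value: float, proc: MAProcedure, warmup: bool) -> AlarmDirection:
    if warmup:
        return AlarmDirection.none
    if ma_value < proc.control_lower:
        return AlarmDirection.lower
    if ma_value > proc.control_upper:
        return AlarmDirection.upper
    return AlarmDirection.none


def process_stream(
    results: Iterable[PatientResult],
    proc: MAProcedure,
    registry: Optional[ExclusionRegistry] = None,
    engine=None,
    start_index: int = 0,
) -> tuple[list[MAPoint], list[MAPoint]]:
    """Run a time-ordered result stream through an MA procedure.

    Produces one :class:`MAPoint` per *included* result; excluded results
    (QC material, excluded patients, values outside truncation) leave the
    engine state untouched and yield no point. Returns
    ``(ma_points, alarms)`` where ``alarms`` is the subset of points whose
    MA value fell strictly outside the control limits.

    ``engine`` and ``start_index`` allow resuming a monitoring session
    (state persists across days; the calculation is continuous, with no
    daily reset).
    """
    if engine is None:
        engine = make_engine(proc)
    points: list[MAPoint] = []
    alarms: list[MAPoint] = []
    index = start_index
    for result in results:
        if not is_includable(result, proc, registry):
            continue
        ma_value, warmup = engine.update(result.value)
        alarm = _alarm_direction(ma_value, proc, warmup)
        point = MAPoint(
            index=index,
            source_result=result,
            ma_value=ma_value,
            alarm=alarm,
            warmup=warmup,
        )
        points.append(point)
        if point.is_alarm:
            alarms.append(point)
        index += 1
    return points, alarms
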