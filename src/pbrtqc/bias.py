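"""Bias-detection simulation: injection, detection counts, validation charts.

To optimize and validate an MA procedure, a step-shaped analytical bias is
injected into a stable result stream and the number of results needed until
the first MA alarm is recorded. Repeating this over many onset positions
yields an *MA validation chart* (min/median/max results-to-detection for one
bias size); sweeping the bias size yields a *bias detection curve*. The
median is interpreted as: in half of the cases the bias is caught in fewer
results than that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from pbrtqc.engine import is_includable, make_engine, process_stream
from pbrtqc.types import ExclusionRegistry, Formula, MAProcedure, PatientResult

__all__ = [
    "BiasScenario",
    "ValidationSummary",
    "DetectionCurve",
    "inject_bias",
    "results_to_detection",
    "validation_chart",
    "bias_detection_curve",
    "default_bias_grid",
]

#: bias range explored during optimization, in percent
BIAS_RANGE = (-50.0, 50.0)


@dataclass(frozen=True)
class BiasScenario:
    """One simulated bias episode: size, onset position, replicate identity."""

    bias_pct: float
    insertion_index: int
    replicate_id: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.insertion_index < 0:
            raise ValueError("insertion_index must be >= 0")


@dataclass(frozen=True)
class ValidationSummary:
    """Results-to-detection statistics for one (procedure, bias) pair.

    ``min/median/max_results`` aggregate over *detecting* replicates only;
    replicates whose stream ended before an alarm are counted as
    ``censored``. The median of an even number of integer counts is the
    lower of the two central values, keeping the statistic integer-valued.
    """

    bias_pct: float
    n_replicates: int
    detections: int
    censored: int
    min_results: Optional[int] = None
    median_results: Optional[int] = None
    max_results: Optional[int] = None

    def __post_init__(self) -> None:
        if self.detections + self.censored != self.n_replicates:
            raise ValueError("detections + censored must equal n_replicates")
        if self.detections > 0:
            if not (self.min_results <= self.median_results <= self.max_results):
                raise ValueError("min <= median <= max violated")


@dataclass
class DetectionCurve:
    """Detection performance across an ordered grid of bias sizes."""

    summaries: list = field(default_factory=list)  # list[tuple[float, ValidationSummary]]

    def __post_init__(self) -> None:
        biases = [b for b, _ in self.summaries]
        if any(b2 <= b1 for b1, b2 in zip(biases, biases[1:])):
            raise ValueError("bias values must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per bias size."""
        rows = []
        for bias, s in self.summaries:
            rows.append(
                {
                    "bias_pct": bias,
                    "min": s.min_results,
                    "median": s.median_results,
                    "max": s.max_results,
                    "detections": s.detections,
                    "censored": s.censored,
                }
            )
        return pd.DataFrame(rows)


def inject_bias(
    stream: Sequence[PatientResult], bias_pct: float, insertion_index: int = 0
) -> list[PatientResult]:
    """Apply a multiplicative step bias to a result stream.

    Results before ``insertion_index`` are returned unchanged; from the
    onset onward each value becomes ``value * (1 + bias_pct / 100)``.
    Identifiers, timestamps and flags are preserved; the input is not
    mutated. Bias is applied to the raw value, *before* any truncation
    check — a biased value may newly fall outside the truncation limits,
    exactly as a real analytical shift would.
    """
    if not -50.0 - 1e-12 <= bias_pct <= 50.0 + 1e-12:
        warnings.warn(
            f"bias of {bias_pct:+g}% is outside the studied -50%..+50% range",
            stacklevel=2,
        )
    if insertion_index < 0 or insertion_index > len(stream):
        raise ValueError("insertion_index out of stream bounds")
    if bias_pct == 0:
        return list(stream)
    factor = 1.0 + bias_pct / 100.0
    out = list(stream[:insertion_index])
    out.extend(r.with_value(r.value * factor) for r in stream[insertion_index:])
    return out


def results_to_detection(
    proc: MAProcedure,
    stream: Sequence[PatientResult],
    scenario: BiasScenario,
    registry: Optional[ExclusionRegistry] = None,
) -> Optional[int]:
    """Number of biased results needed until the first MA alarm.

    The engine is warm-started on the unbiased prefix of the stream up to
    the onset position, then fed the biased remainder. Returns the count of
    *included, biased* results processed from the onset up to and including
    the first alarming MA point, or ``None`` if the stream ends without an
    alarm (censored). Alarms occurring before the onset are ignored: the
    quantity measured is the response to the injected bias.
    """
    idx = scenario.insertion_index
    if idx > len(stream):
        raise ValueError("insertion_index beyond end of stream")
    engine = make_engine(proc)
    prefix_points, _ = process_stream(stream[:idx], proc, registry, engine=engine)
    n_included = len(prefix_points)

    factor = 1.0 + scenario.bias_pct / 100.0
    count = 0
    index = n_included
    for result in stream[idx:]:
        biased = result.with_value(result.value * factor)
        if not is_includable(biased, proc, registry):
            continue
        ma_value, warmup = engine.update(biased.value)
        count += 1
        index += 1
        if not warmup and (ma_value < proc.control_lower or ma_value > proc.control_upper):
            return count
    return None


def _warmup_length(proc: MAProcedure) -> int:
    return proc.block_size if proc.formula is Formula.simple else 1


def _lower_median(counts: Sequence[int]) -> int:
    # integer-valued statistic: lower of the two central values for even n
    ordered = sorted(counts)
    return ordered[(len(ordered) - 1) // 2]


def validation_chart(
    proc: MAProcedure,
    stream: Sequence[PatientResult],
    bias_pct: float,
    n_replicates: int = 100,
    rng_seed: int = 0,
    registry: Optional[ExclusionRegistry] = None,
) -> ValidationSummary:
    """Simulate ``n_replicates`` bias episodes and summarize detection.

    Each replicate draws its onset position uniformly over the post-warm-up
    region of the stream; everything is reproducible from ``rng_seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    lo = _warmup_length(proc)
    hi = len(stream) - 1
    if hi < lo:
        raise ValueError(
            f"stream of {len(stream)} results is shorter than the warm-up "
            f"of {lo} required by the procedure"
        )
    rng = np.random.default_rng(rng_seed)
    onsets = rng.integers(lo, hi + 1, size=n_replicates)
    counts: list[int] = []
    censored = 0
    for rep, onset in enumerate(onsets):
        scenario = BiasScenario(
            bias_pct=bias_pct, insertion_index=int(onset), replicate_id=rep
        )
        c = results_to_detection(proc, stream, scenario, registry)
        if c is None:
            censored += 1
        else:
            counts.append(c)
    if counts:
        return ValidationSummary(
            bias_pct=bias_pct,
            n_replicates=n_replicates,
            detections=len(counts),
            censored=censored,
            min_results=min(counts),
            median_results=_lower_median(counts),
            max_results=max(counts),
        )
    return ValidationSummary(
        bias_pct=bias_pct,
        n_replicates=n_replicates,
        detections=0,
        censored=censored,
    )


def default_bias_grid(tea_pct: Optional[float] = None) -> list[float]:
    """-50% .. +50% in steps of 5, plus the analyte's +/-TEa if given."""
    grid = set(range(-50, 55, 5))
    if tea_pct is not None:
        grid.update({-abs(tea_pct), abs(tea_pct)})
    return sorted(float(b) for b in grid)


def bias_detection_curve(
    proc: MAProcedure,
    stream: Sequence[PatientResult],
    biases: Optional[Iterable[float]] = None,
    n_replicates: int = 100,
    rng_seed: int = 0,
    tea_pct: Optional[float] = None,
    registry: Optional[ExclusionRegistry] = None,
) -> DetectionCurve:
    """Validation summaries across a grid of bias sizes.

    ``biases`` must be sorted strictly increasing; by default the grid is
    -50..+50 in steps of 5 plus the analyte's +/-TEa. All bias sizes share
    the same replicate onset positions (common random numbers), so points
    on the curve are directly comparable.
    """
    grid = list(biases) if biases is not None else default_bias_grid(tea_pct)
    if not grid:
        raise ValueError("bias grid is empty")
    summaries = [
        (bias, validation_chart(proc, stream, bias, n_replicates, rng_seed, registry))
        for bias in grid
    ]
    return DetectionCurve(summaries)
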