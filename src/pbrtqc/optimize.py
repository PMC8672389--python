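"""Candidate-grid search for optimal MA procedures.

A procedure is optimized by enumerating combinations of calculation formula
(simple MA / EWMA), block size or weighting factor, and truncation limits;
deriving control limits as the min/max of the MA over a stable training
stream; and simulating bias detection at +/-TEa. The key acceptance
criterion is the ability to detect a bias the size of the total allowable
error within the laboratory's average daily number of tests for the
analyte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from pbrtqc.bias import ValidationSummary, validation_chart
from pbrtqc.engine import is_includable, process_stream
from pbrtqc.types import (
    AnalyteConfig,
    ExclusionRegistry,
    Formula,
    MAPoint,
    MAProcedure,
    PatientResult,
)

__all__ = [
    "CandidateGrid",
    "CandidatePerformance",
    "derive_control_limits",
    "enumerate_candidates",
    "evaluate_candidates",
    "select_optimal",
    "verify_limits",
]

#: defaults mirroring block sizes and weighting factors commonly selected
#: for clinical chemistry analytes
DEFAULT_BLOCK_SIZES = (10, 25, 100)
DEFAULT_WEIGHTING_FACTORS = (0.05, 0.1)


@dataclass(frozen=True)
class CandidateGrid:
    """Cartesian grid of MA-procedure parameters to examine.

    ``truncation_options`` is a list of ``(lower, upper)`` pairs where
    ``None`` means unbounded; ``(None, None)`` is "no truncation".
    """

    formulas: tuple = (Formula.simple, Formula.ewma)
    block_sizes: tuple = DEFAULT_BLOCK_SIZES
    weighting_factors: tuple = DEFAULT_WEIGHTING_FACTORS
    truncation_options: tuple = ((None, None),)

    def __post_init__(self) -> None:
        if not self.formulas or not self.truncation_options:
            raise ValueError("grid must contain at least one candidate")
        if Formula.simple in self.formulas and not self.block_sizes:
            raise ValueError("simple MA in grid but no block sizes")
        if Formula.ewma in self.formulas and not self.weighting_factors:
            raise ValueError("EWMA in grid but no weighting factors")
        if any(n < 1 for n in self.block_sizes):
            raise ValueError("block sizes must be >= 1")
        if any(not 0 < lam <= 1 for lam in self.weighting_factors):
            raise ValueError("weighting factors must be in (0, 1]")


@dataclass(frozen=True)
class CandidatePerformance:
    """Bias-detection performance of one candidate at +/-TEa."""

    procedure: MAProcedure
    summary_pos: ValidationSummary
    summary_neg: ValidationSummary
    passes: bool


def derive_control_limits(ma_points: Sequence[MAPoint]) -> tuple[float, float]:
    """Control limits as the (min, max) MA value over a stable period.

    Warm-up points are ignored. With limits set to the attained extremes,
    replaying the very same stream produces zero alarms — false alarms in
    routine use are almost completely avoided.
    """
    values = [p.ma_value for p in ma_points if not p.warmup]
    if not values:
        raise ValueError("no non-warm-up MA points to derive limits from")
    return min(values), max(values)


def _candidate_procedures(
    grid: CandidateGrid, analyte: AnalyteConfig, ewma_seed: float
) -> list[MAProcedure]:
    procs = []
    for formula in grid.formulas:
        params = grid.block_sizes if formula is Formula.simple else grid.weighting_factors
        for param in params:
            for lower, upper in grid.truncation_options:
                procs.append(
                    MAProcedure(
                        analyte_name=analyte.analyte_name,
                        formula=formula,
                        block_size=param if formula is Formula.simple else None,
                        weighting_factor=param if formula is Formula.ewma else None,
                        truncation_lower=lower,
                        truncation_upper=upper,
                        control_lower=-np.inf,
                        control_upper=np.inf,
                        ewma_seed=ewma_seed if formula is Formula.ewma else None,
                    )
                )
    return procs


def enumerate_candidates(
    grid: CandidateGrid,
    training_stream: Sequence[PatientResult],
    analyte: AnalyteConfig,
    registry: Optional[ExclusionRegistry] = None,
) -> list[MAProcedure]:
    """Expand the grid into fully parameterized candidate procedures.

    Each candidate is completed with control limits derived from the
    training stream (min/max MA after warm-up, computed under that
    candidate's own truncation limits) and, for EWMA, a seed equal to the
    mean of the training stream's included values.
    """
    if not training_stream:
        raise ValueError("training stream is empty")
    candidates = []
    for proc in _candidate_procedures(grid, analyte, ewma_seed=0.0):
        included = [
            r.value for r in training_stream if is_includable(r, proc, registry)
        ]
        if not included:
            continue
        if proc.formula is Formula.ewma:
            proc = proc.model_copy(update={"ewma_seed": float(np.mean(included))})
        points, _ = process_stream(training_stream, proc, registry)
        lower, upper = derive_control_limits(points)
        candidates.append(proc.with_limits(lower, upper))
    if not candidates:
        raise ValueError("no candidate admitted any training result")
    return candidates


def evaluate_candidates(
    candidates: Sequence[MAProcedure],
    training_stream: Sequence[PatientResult],
    analyte: AnalyteConfig,
    n_replicates: int = 100,
    rng_seed: int = 0,
    registry: Optional[ExclusionRegistry] = None,
) -> list[CandidatePerformance]:
    """Simulate +/-TEa bias detection for every candidate.

    A candidate *passes* when its median results-to-detection at both
    +TEa and -TEa is within the analyte's daily test volume (and at least
    half its replicates detect, so the median is defined).
    """
    performances = []
    for proc in candidates:
        pos = validation_chart(
            proc, training_stream, +analyte.tea_pct, n_replicates, rng_seed, registry
        )
        neg = validation_chart(
            proc, training_stream, -analyte.tea_pct, n_replicates, rng_seed, registry
        )
        passes = all(
            s.median_results is not None
            and s.detections * 2 >= s.n_replicates
            and s.median_results <= analyte.daily_volume
            for s in (pos, neg)
        )
        performances.append(CandidatePerformance(proc, pos, neg, passes))
    return performances


def _objective(perf: CandidatePerformance) -> tuple:
    big = float("inf")
    pos, neg = perf.summary_pos, perf.summary_neg
    median_sum = (
        (pos.median_results + neg.median_results)
        if pos.median_results is not None and neg.median_results is not None
        else big
    )
    max_sum = (
        (pos.max_results + neg.max_results)
        if pos.max_results is not None and neg.max_results is not None
        else big
    )
    proc = perf.procedure
    # tie-break: smaller block size, then larger weighting factor
    param = (
        proc.block_size
        if proc.formula is Formula.simple
        else -proc.weighting_factor
    )
    return median_sum, max_sum, param


def select_optimal(
    performances: Sequence[CandidatePerformance],
    analyte: AnalyteConfig,
) -> MAProcedure:
    """Pick the candidate with the best +/-TEa detection performance.

    Among passing candidates, minimizes the median results-to-detection
    summed over both bias directions; ties broken by smaller summed
    maximum, then smaller block size / larger weighting factor, then
    declaration order. If no candidate passes, the best non-passing one is
    returned with a warning.
    """
    if not performances:
        raise ValueError("no candidate performances supplied")
    passing = [p for p in performances if p.passes]
    pool = passing or list(performances)
    if not passing:
        warnings.warn(
            f"no candidate for {analyte.analyte_name} detects +/-{analyte.tea_pct}% "
            f"bias within the daily volume of {analyte.daily_volume}; "
            "returning the best non-passing candidate",
            stacklevel=2,
        )
    best = min(range(len(pool)), key=lambda i: (_objective(pool[i]), i))
    return pool[best].procedure


def verify_limits(
    proc: MAProcedure,
    stream: Sequence[PatientResult],
    registry: Optional[ExclusionRegistry] = None,
) -> pd.Series:
    """Check established control limits against a later stable period.

    Recomputes the MA over ``stream`` and reports the attained MA range,
    the configured limits, the number of alarms on replay, and whether the
    limits still contain the stable-period MA (i.e. no correction needed).
    """
    points, alarms = process_stream(stream, proc, registry)
    lower, upper = derive_control_limits(points)
    within = proc.control_lower <= lower and upper <= proc.control_upper
    return pd.Series(
        {
            "analyte": proc.analyte_name,
            "ma_min": lower,
            "ma_max": upper,
            "control_lower": proc.control_lower,
            "control_upper": proc.control_upper,
            "n_ma_values": len(points),
            "n_alarms": len(alarms),
            "within_limits": within,
        }
    )
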