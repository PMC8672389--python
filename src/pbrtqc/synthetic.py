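"""Synthetic outpatient result streams.

Emulates the per-analyte result flow of a small outpatient laboratory:
approximately unimodal value distributions (normal or lognormal) truncated
to a physiologic range, a configurable rate of pathological outliers,
patient revisits, and superimposable artifacts — chronic pathological
patients, saline-diluted or lipemic/haemolysed samples, and step-shaped
analytical shifts. Streams are the test bed for the MA engines and the
bias-detection simulations; they do not attempt multivariate correlation
between analytes or seasonal structure.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from pbrtqc.bias import inject_bias
from pbrtqc.types import PatientResult

__all__ = [
    "PopulationSpec",
    "ArtifactKind",
    "ArtifactSpec",
    "generate_stream",
    "apply_artifact",
    "load_population_specs",
]

_WORKDAY_START_HOUR = 8
_WORKDAY_HOURS = 8.0
_MAX_REJECTION_ROUNDS = 100


@dataclass(frozen=True)
class PopulationSpec:
    """Distribution of one analyte in the served patient population.

    ``mean`` and ``cv_pct`` parameterize the underlying distribution
    before physiologic rejection; ``lower/upper_physiologic`` bound the
    base draw. Outliers are injected afterwards at ``outlier_rate`` by a
    multiplicative factor drawn uniformly from ``outlier_factor_range``
    (use factors < 1 for low-side pathology), and may exceed the
    physiologic bounds, as genuinely pathological samples do.
    """

    analyte_name: str
    units: str
    mean: float
    cv_pct: float
    distribution: str = "normal"
    lower_physiologic: float = -math.inf
    upper_physiologic: float = math.inf
    outlier_rate: float = 0.0
    outlier_factor_range: tuple = (1.5, 3.0)

    def __post_init__(self) -> None:
        if self.cv_pct <= 0:
            raise ValueError("cv_pct must be > 0")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError("distribution must be 'normal' or 'lognormal'")
        if not self.lower_physiologic < self.upper_physiologic:
            raise ValueError("physiologic bounds must be ordered")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")
        lo, hi = self.outlier_factor_range
        if not 0 < lo <= hi:
            raise ValueError("outlier_factor_range must satisfy 0 < low <= high")


class ArtifactKind(str, enum.Enum):
    saline_dilution = "saline_dilution"
    lipemia = "lipemia"
    hemolysis = "hemolysis"
    chronic_pathological_patient = "chronic_pathological_patient"
    step_shift = "step_shift"


_REQUIRED_PARAMS = {
    ArtifactKind.saline_dilution: {"sample_id", "factor"},
    ArtifactKind.lipemia: {"sample_ids", "factor"},
    ArtifactKind.hemolysis: {"sample_ids", "factor"},
    ArtifactKind.chronic_pathological_patient: {"patient_id", "factor"},
    ArtifactKind.step_shift: {"bias_pct", "onset_index"},
}


@dataclass(frozen=True)
class ArtifactSpec:
    """One injectable data artifact, parameterized by kind.

    Required parameters per kind:

    * ``saline_dilution`` — ``sample_id``, ``factor`` (multiplier for the
      diluted sample's value: > 1 for sodium approaching saline, < 1 for
      analytes the saline dilutes out);
    * ``lipemia`` / ``hemolysis`` — ``sample_ids``, ``factor``; sets the
      L/H interference flag on the targeted samples and perturbs values;
    * ``chronic_pathological_patient`` — ``patient_id``, ``factor``
      applied to every result of that patient;
    * ``step_shift`` — ``bias_pct``, ``onset_index``: a persistent
      analytical shift on all results from the onset onward.
    """

    kind: ArtifactKind
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = _REQUIRED_PARAMS[ArtifactKind(self.kind)] - set(self.parameters)
        if missing:
            raise ValueError(
                f"artifact {self.kind} missing parameters: {sorted(missing)}"
            )


def _draw_base(
    spec: PopulationSpec, size: int, rng: np.random.Generator
) -> np.ndarray:
    sd = spec.mean * spec.cv_pct / 100.0
    if spec.distribution == "normal":
        return rng.normal(spec.mean, sd, size)
    cv = spec.cv_pct / 100.0
    sigma2 = math.log1p(cv * cv)
    mu = math.log(spec.mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _rejection_sample(
    spec: PopulationSpec, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` values inside the physiologic bounds."""
    out = np.empty(0)
    for _ in range(_MAX_REJECTION_ROUNDS):
        need = size - out.size
        if need <= 0:
            return out[:size]
        draw = _draw_base(spec, max(need * 2, 16), rng)
        keep = draw[
            (draw >= spec.lower_physiologic) & (draw <= spec.upper_physiologic)
        ]
        out = np.concatenate([out, keep])
    raise RuntimeError(
        f"rejection sampling for {spec.analyte_name} failed: physiologic bounds "
        f"[{spec.lower_physiologic}, {spec.upper_physiologic}] admit almost no "
        "probability mass"
    )


def generate_stream(
    spec: PopulationSpec,
    n_days: int,
    tests_per_day: int,
    rng_seed: int = 0,
    revisit_rate: float = 0.1,
    start: Optional[datetime] = None,
) -> list[PatientResult]:
    """Generate a time-ordered synthetic result stream.

    ``tests_per_day`` results per working day are spread evenly over an
    8-hour workday. Sample IDs are unique; patient IDs repeat at
    ``revisit_rate`` (a revisiting patient is drawn uniformly from those
    already seen), exercising the patient-exclusion machinery downstream.
    Fully reproducible from ``rng_seed``.
    """
    if n_days < 0 or tests_per_day < 0:
        raise ValueError("n_days and tests_per_day must be >= 0")
    if not 0 <= revisit_rate < 1:
        raise ValueError("revisit_rate must be in [0, 1)")
    total = n_days * tests_per_day
    if total == 0:
        return []
    if start is None:
        start = datetime(2024, 1, 1, _WORKDAY_START_HOUR, 0, 0)

    rng = np.random.default_rng(rng_seed)
    values = _rejection_sample(spec, total, rng)
    is_outlier = rng.random(total) < spec.outlier_rate
    lo, hi = spec.outlier_factor_range
    factors = rng.uniform(lo, hi, total)
    values = np.where(is_outlier, values * factors, values)
    revisits = rng.random(total) < revisit_rate
    revisit_choice = rng.random(total)

    step = timedelta(hours=_WORKDAY_HOURS / max(tests_per_day, 1))
    results: list[PatientResult] = []
    seen_patients: list[str] = []
    k = 0
    for day in range(n_days):
        day_start = start + timedelta(days=day)
        for i in range(tests_per_day):
            if revisits[k] and seen_patients:
                patient_id = seen_patients[
                    int(revisit_choice[k] * len(seen_patients))
                ]
            else:
                patient_id = f"P{k:06d}"
                seen_patients.append(patient_id)
            results.append(
                PatientResult(
                    sample_id=f"S{day:04d}-{i:04d}",
                    patient_id=patient_id,
                    timestamp=day_start + i * step,
                    analyte_name=spec.analyte_name,
                    value=float(values[k]),
                )
            )
            k += 1
    return results


def _with_flag(result: PatientResult, flag: str, factor: float) -> PatientResult:
    return PatientResult(
        sample_id=result.sample_id,
        patient_id=result.patient_id,
        timestamp=result.timestamp,
        analyte_name=result.analyte_name,
        value=result.value * factor,
        hil_flags=result.hil_flags | {flag},
        is_control=result.is_control,
    )


def apply_artifact(
    stream: Sequence[PatientResult],
    artifact: ArtifactSpec,
    rng_seed: int = 0,
) -> list[PatientResult]:
    """Realize an artifact on a stream; untouched results are identical.

    Raises ``KeyError`` when a referenced sample or patient does not occur
    in the stream.
    """
    kind = ArtifactKind(artifact.kind)
    params = artifact.parameters

    if kind is ArtifactKind.step_shift:
        return inject_bias(stream, params["bias_pct"], params["onset_index"])

    if kind is ArtifactKind.chronic_pathological_patient:
        pid = params["patient_id"]
        if not any(r.patient_id == pid for r in stream):
            raise KeyError(f"patient {pid!r} not present in stream")
        factor = params["factor"]
        return [
            r.with_value(r.value * factor) if r.patient_id == pid else r
            for r in stream
        ]

    if kind is ArtifactKind.saline_dilution:
        sid = params["sample_id"]
        if not any(r.sample_id == sid for r in stream):
            raise KeyError(f"sample {sid!r} not present in stream")
        factor = params["factor"]
        return [
            r.with_value(r.value * factor) if r.sample_id == sid else r
            for r in stream
        ]

    # lipemia / hemolysis: flag + perturb the targeted samples
    flag = "L" if kind is ArtifactKind.lipemia else "H"
    targets = set(params["sample_ids"])
    present = {r.sample_id for r in stream}
    missing = targets - present
    if missing:
        raise KeyError(f"samples not present in stream: {sorted(missing)}")
    factor = params["factor"]
    return [
        _with_flag(r, flag, factor) if r.sample_id in targets else r
        for r in stream
    ]


def load_population_specs(path: Optional[str] = None) -> dict:
    """Load population specs from YAML (packaged: ``data/populations.yaml``)."""
    if path is None:
        text = resources.files("pbrtqc.data").joinpath("populations.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    specs = {}
    for name, entry in raw.items():
        specs[name] = PopulationSpec(
            analyte_name=name,
            units=entry.get("units", ""),
            mean=entry["mean"],
            cv_pct=entry["cv_pct"],
            distribution=entry.get("distribution", "normal"),
            lower_physiologic=entry.get("lower_physiologic", -math.inf),
            upper_physiologic=entry.get("upper_physiologic", math.inf),
            outlier_rate=entry.get("outlier_rate", 0.0),
            outlier_factor_range=tuple(entry.get("outlier_factor_range", (1.5, 3.0))),
        )
    return specs
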