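from datetime import datetime, timedelta

import pytest

from pbrtqc.config import load_procedures
from pbrtqc.engine import process_stream
from pbrtqc.optimize import derive_control_limits
from pbrtqc.synthetic import load_population_specs, generate_stream
from pbrtqc.types import PatientResult


def make_stream(values, analyte="sodium", start=None, patient_ids=None):
    """Hand-build a time-ordered stream from raw values."""
    start = start or datetime(2024, 3, 1, 8, 0)
    out = []
    for i, v in enumerate(values):
        out.append(
            PatientResult(
                sample_id=f"S{i:05d}",
                patient_id=patient_ids[i] if patient_ids else f"P{i:05d}",
                timestamp=start + timedelta(minutes=10 * i),
                analyte_name=analyte,
                value=float(v),
            )
        )
    return out


@pytest.fixture(scope="session")
def procedures():
    return load_procedures()


@pytest.fixture(scope="session")
def population_specs():
    return load_population_specs()


@pytest.fixture(scope="session")
def sodium_training(population_specs):
    """30 working days of a stable sodium-like outpatient stream."""
    return generate_stream(population_specs["sodium"], 30, 39, rng_seed=20240301)


@pytest.fixture(scope="session")
def sodium_proc(procedures, sodium_training):
    """Sodium procedure with control limits derived from the training stream."""
    proc, _ = procedures["sodium"]
    points, _ = process_stream(sodium_training, proc)
    lower, upper = derive_control_limits(points)
    return proc.with_limits(lower, upper)


@pytest.fixture(scope="session")
def sodium_analyte(procedures):
    return procedures["sodium"][1]
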