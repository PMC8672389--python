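"""Streaming MA/EWMA calculators, inclusion rules, alarm generation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pbrtqc.engine import (
    EwmaEngine,
    SimpleMAEngine,
    ewma_step,
    is_includable,
    process_stream,
    simple_ma_step,
)
from pbrtqc.optimize import derive_control_limits
from pbrtqc.types import ExclusionRegistry, MAProcedure, PatientResult

from conftest import make_stream


def simple_proc(n=3, lower=0.0, upper=1000.0, analyte="sodium", **kw):
    return MAProcedure(
        analyte_name=analyte, formula="simple", block_size=n,
        control_lower=lower, control_upper=upper, **kw,
    )


def ewma_proc(lam=0.1, seed=139.5, lower=0.0, upper=1000.0, analyte="sodium", **kw):
    return MAProcedure(
        analyte_name=analyte, formula="ewma", weighting_factor=lam,
        ewma_seed=seed, control_lower=lower, control_upper=upper, **kw,
    )


class TestInclusion:
    def test_value_above_upper_truncation_is_excluded(self):
        proc = simple_proc(n=100, analyte="ast", truncation_upper=50.0)
        (r,) = make_stream([60.0], analyte="ast")
        assert not is_includable(r, proc)

    def test_unbounded_procedure_includes_everything(self):
        (r,) = make_stream([139.0])
        assert is_includable(r, simple_proc())

    def test_control_material_never_included(self):
        (r,) = make_stream([139.0])
        control = PatientResult(
            sample_id="QC1", patient_id="QC", timestamp=r.timestamp,
            analyte_name="sodium", value=139.0, is_control=True,
        )
        assert not is_includable(control, simple_proc())

    def test_boundary_values_on_truncation_limit_are_included(self):
        proc = simple_proc(truncation_lower=130.0, truncation_upper=150.0)
        lo, hi = make_stream([130.0, 150.0])
        assert is_includable(lo, proc) and is_includable(hi, proc)

    def test_registered_patient_is_excluded_idempotently(self):
        registry = ExclusionRegistry()
        registry.exclude("P1", "sodium", "chronic")
        registry.exclude("P1", "sodium", "chronic")  # no effect
        assert len(registry) == 1
        (r,) = make_stream([139.0], patient_ids=["P1"])
        assert not is_includable(r, simple_proc(), registry)

    def test_analyte_mismatch_is_a_contract_violation(self):
        (r,) = make_stream([5.0], analyte="potassium")
        with pytest.raises(ValueError, match="analyte mismatch"):
            is_includable(r, simple_proc(analyte="sodium"))


class TestSimpleMA:
    def test_constant_stream_gives_constant_mean(self):
        state = []
        for _ in range(10):
            state, ma, _ = simple_ma_step(state, 5.0, 4)
            assert ma == 5.0

    def test_mean_of_full_window(self):
        state = []
        for x in (100.0, 110.0, 120.0):
            state, ma, warmup = simple_ma_step(state, x, 3)
        assert ma == 110.0 and not warmup

    def test_warmup_flag_until_window_full(self):
        state = []
        flags = []
        for x in range(5):
            state, _, warmup = simple_ma_step(state, float(x), 3)
            flags.append(warmup)
        assert flags == [True, True, False, False, False]

    def test_non_finite_value_rejected(self):
        with pytest.raises(ValueError):
            simple_ma_step([], math.nan, 3)

    @pytest.mark.parametrize("n", [1, 5, 10, 25, 100])
    def test_streaming_engine_matches_trailing_window_oracle(self, n):
        rng = np.random.default_rng(42 + n)
        values = rng.normal(100.0, 10.0, 2000)
        engine = SimpleMAEngine(n)
        got = np.array([engine.update(x)[0] for x in values])
        # independent oracle: pandas rolling mean with expanding warm-up
        expect = pd.Series(values).rolling(n, min_periods=1).mean().to_numpy()
        np.testing.assert_allclose(got, expect, rtol=1e-12)


class TestEwma:
    def test_full_weight_on_current_value(self):
        assert ewma_step(99.9, 7.2, 1.0) == 7.2

    def test_one_tenth_weighting(self):
        assert ewma_step(140.0, 150.0, 0.1) == pytest.approx(141.0)

    def test_invalid_weighting_factor_rejected(self):
        for lam in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                ewma_step(1.0, 1.0, lam)

    @settings(max_examples=50, derandomize=True)
    @given(
        lam=st.floats(0.01, 1.0),
        seed=st.floats(-100, 100),
        xs=st.lists(st.floats(-100, 100), min_size=1, max_size=30),
    )
    def test_iteration_equals_closed_form_expansion(self, lam, seed, xs):
        engine = EwmaEngine(lam, seed)
        for x in xs:
            z, _ = engine.update(x)
        k = len(xs)
        closed = lam * sum(
            (1 - lam) ** i * xs[k - 1 - i] for i in range(k)
        ) + (1 - lam) ** k * seed
        assert z == pytest.approx(closed, rel=1e-9, abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(
        seed=st.floats(-50, 50),
        xs=st.lists(st.floats(-50, 50), min_size=1, max_size=50),
    )
    def test_ewma_stays_within_seed_and_observation_range(self, seed, xs):
        engine = EwmaEngine(0.2, seed)
        lo, hi = min([seed] + xs), max([seed] + xs)
        for x in xs:
            z, _ = engine.update(x)
            assert lo - 1e-9 <= z <= hi + 1e-9

    def test_lambda_one_reproduces_raw_stream(self):
        stream = make_stream([140.0, 138.5, 141.2, 139.9])
        proc = ewma_proc(lam=1.0)
        points, _ = process_stream(stream, proc)
        assert [p.ma_value for p in points] == [r.value for r in stream]


class TestProcessStream:
    def test_empty_stream_yields_empty_outputs(self):
        points, alarms = process_stream([], simple_proc())
        assert points == [] and alarms == []

    def test_one_point_per_included_result_with_running_index(self):
        stream = make_stream([139.0, 140.0, 138.0])
        points, _ = process_stream(stream, simple_proc())
        assert [p.index for p in points] == [0, 1, 2]
        assert [p.source_result for p in points] == stream

    def test_excluded_results_leave_ma_sequence_unchanged(self):
        proc = simple_proc(n=3, truncation_lower=130.0, truncation_upper=150.0)
        registry = ExclusionRegistry()
        registry.exclude("BAD", "sodium")
        values = [139.0, 170.0, 140.0, 138.0, 100.0, 141.0, 139.5]
        pids = ["P0", "P1", "BAD", "P3", "P4", "P5", "P6"]
        stream = make_stream(values, patient_ids=pids)
        kept = [
            r for r in stream
            if 130.0 <= r.value <= 150.0 and r.patient_id != "BAD"
        ]
        full_points, _ = process_stream(stream, proc, registry)
        kept_points, _ = process_stream(kept, proc, registry)
        assert [p.ma_value for p in full_points] == [p.ma_value for p in kept_points]
        assert [p.source_result.sample_id for p in full_points] == [
            r.sample_id for r in kept
        ]

    def test_replaying_training_stream_against_own_limits_never_alarms(
        self, sodium_training, sodium_proc
    ):
        _, alarms = process_stream(sodium_training, sodium_proc)
        assert alarms == []

    def test_ewma_alarm_fires_at_first_recursion_crossing(self):
        # every value above the upper limit: find the analytic crossing
        proc = ewma_proc(lam=0.1, seed=139.5, lower=137.0, upper=142.0)
        stream = make_stream([150.0] * 50)
        points, alarms = process_stream(stream, proc)
        # direct recursion oracle
        z, first = 139.5, None
        for i in range(50):
            z = 0.1 * 150.0 + 0.9 * z
            if z > 142.0:
                first = i
                break
        assert first is not None
        assert alarms[0].index == first
        assert all(p.alarm.value == "none" for p in points[:first])

    def test_warmup_points_are_not_alarm_eligible(self):
        # first values far outside limits, but window not yet full
        proc = simple_proc(n=5, lower=137.0, upper=142.0)
        stream = make_stream([200.0] * 4)
        points, alarms = process_stream(stream, proc)
        assert all(p.warmup for p in points)
        assert alarms == []

    def test_limits_derived_from_ma_points_bound_every_value(self, sodium_training):
        proc = simple_proc(n=25)
        points, _ = process_stream(sodium_training, proc)
        lower, upper = derive_control_limits(points)
        eligible = [p.ma_value for p in points if not p.warmup]
        assert lower == min(eligible) and upper == max(eligible)
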