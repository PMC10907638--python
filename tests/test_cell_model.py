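"""Cell-model contract: beating, calcium handling, and the n*b identity."""

import math

import numpy as np
import pytest

from calreg.cell_model import (
    CellModel,
    DrugBlock,
    MinimalHiPSCCM,
    Trace,
    compute_target_calcium,
    cycle_average_calcium,
    ical_scaling,
    limit_cycle_init,
    run_fixed_n,
)
from calreg.cell_model import _upstroke_times_from_arrays
from calreg.errors import InvalidParameterError, NumericalStateError


class MockConstantCalcium(CellModel):
    """Beating voltage oscillator with constant cytosolic calcium.

    Oracle for the target-calcium computation: the cycle average of a
    constant is that constant, whatever the cycle boundaries.
    """

    state_names = ("V", "c")
    protein_types = ("CaL", "Na", "f", "Kr", "K1", "SERCA")

    def __init__(self, c_const=2e-4, period_ms=1000.0):
        self.c_const = c_const
        self.period_ms = period_ms

    def default_state(self):
        return np.array([-80.0, self.c_const])

    def derivatives(self, state, t=0.0, scales=None, drug=None, n=1.0):
        omega = 2.0 * math.pi / self.period_ms
        dv = 40.0 * omega * math.cos(omega * t)
        return np.array([dv, 0.0])


class TestDrugBlock:
    def test_no_drug_is_identity(self):
        assert ical_scaling(1.0, DrugBlock.none()) == 1.0

    def test_compensated_block_restores_default(self):
        assert ical_scaling(10.0, DrugBlock(1.0, 0.1)) == pytest.approx(1.0)

    def test_one_micromolar_case(self):
        assert ical_scaling(1.0, DrugBlock(1.0, 0.12)) == pytest.approx(0.12)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(InvalidParameterError):
            ical_scaling(0.0, DrugBlock.none())

    def test_block_factor_domain(self):
        with pytest.raises(InvalidParameterError):
            DrugBlock(1.0, 0.0)
        with pytest.raises(InvalidParameterError):
            DrugBlock(1.0, 1.2)


class TestSpontaneousBeating:
    def test_at_least_three_upstrokes_in_ten_seconds(self, model, default_init):
        tr = run_fixed_n(model, 1.0, None, 10_000.0, default_init.state)
        ups = _upstroke_times_from_arrays(tr.time_ms, tr.voltage)
        assert ups.size >= 3

    def test_calcium_positive_and_bounded(self, model, default_init):
        tr = run_fixed_n(model, 1.0, None, 10_000.0, default_init.state)
        assert np.all(tr.calcium > 0)
        assert np.all(tr.calcium < 0.01)

    def test_graded_release_monotone_in_cal_scale(self, model, default_init):
        """Cycle-averaged calcium increases with the CaL density scale."""
        averages = []
        for scale in (0.8, 0.9, 1.0, 1.1, 1.2):
            settle = run_fixed_n(
                model, scale, None, 60_000.0, default_init.state, dt_sample_ms=20.0
            )
            tr = run_fixed_n(
                model, scale, None, 10_000.0, settle.metadata["final_state"]
            )
            cbar, quiescent = cycle_average_calcium(tr)
            assert not quiescent
            averages.append(cbar)
        assert all(a < b for a, b in zip(averages, averages[1:]))


class TestDrugCompensationIdentity:
    def test_derivatives_depend_only_on_product(self, model, default_init):
        rng = np.random.default_rng(0)
        state = default_init.state
        for _ in range(5):
            perturbed = state * (1.0 + 0.05 * rng.standard_normal(state.size))
            perturbed[6] = abs(perturbed[6])  # gates/concentrations positive
            d1 = model.derivatives(perturbed, 0.0, None, DrugBlock(1.0, 0.1), 10.0)
            d2 = model.derivatives(perturbed, 0.0, None, DrugBlock.none(), 1.0)
            assert np.allclose(d1, d2, rtol=1e-12, atol=0.0)

    def test_zero_cal_scale_removes_current(self, model, default_init):
        state = default_init.state
        d_scaled = model.derivatives(state, 0.0, {"CaL": 0.0}, None, 1.0)
        d_tiny = model.derivatives(state, 0.0, {"CaL": 1e-300}, None, 1.0)
        assert np.allclose(d_scaled, d_tiny)

    def test_trace_level_identity(self, model, default_init):
        tr_blocked = run_fixed_n(
            model, 10.0, DrugBlock(1.0, 0.1), 5_000.0, default_init.state
        )
        tr_default = run_fixed_n(model, 1.0, None, 5_000.0, default_init.state)
        assert np.max(np.abs(tr_blocked.voltage - tr_default.voltage)) < 0.5


class TestRunFixedN:
    def test_deterministic_repeat(self, model, default_init):
        tr1 = run_fixed_n(model, 1.0, None, 3_000.0, default_init.state)
        tr2 = run_fixed_n(model, 1.0, None, 3_000.0, default_init.state)
        assert np.array_equal(tr1.voltage, tr2.voltage)
        assert np.array_equal(tr1.calcium, tr2.calcium)

    def test_blocked_cycle_average_below_default(self, model, default_init):
        settle = run_fixed_n(
            model, 1.0, DrugBlock(1.0, 0.12), 60_000.0, default_init.state,
            dt_sample_ms=20.0,
        )
        tr = run_fixed_n(
            model, 1.0, DrugBlock(1.0, 0.12), 10_000.0, settle.metadata["final_state"]
        )
        c_blocked, _ = cycle_average_calcium(tr)
        tr0 = run_fixed_n(model, 1.0, None, 10_000.0, default_init.state)
        c_default, _ = cycle_average_calcium(tr0)
        assert c_blocked < c_default

    def test_invalid_duration_rejected(self, model):
        with pytest.raises(InvalidParameterError):
            run_fixed_n(model, 1.0, None, 0.0)

    def test_nan_state_names_component(self, model):
        bad = model.default_state()
        bad[0] = np.nan
        with pytest.raises(NumericalStateError) as err:
            model.derivatives(bad)
        assert "V" in str(err.value)


class TestLimitCycleInit:
    def test_determinism(self, model):
        i1 = limit_cycle_init(model, 1.0, equilibration_ms=30_000.0)
        i2 = limit_cycle_init(model, 1.0, equilibration_ms=30_000.0)
        assert np.array_equal(i1.state, i2.state)

    def test_underexpressed_average_below_target(self, model, c_star):
        init = limit_cycle_init(model, 0.1)
        assert not init.quiescent
        tr = run_fixed_n(model, 0.1, None, 10_000.0, init.state)
        cbar, _ = cycle_average_calcium(tr)
        assert cbar < c_star

    def test_quiescent_model_flagged_not_raised(self, model):
        # no pacemaker current, no fast sodium: the cell cannot escape rest
        init = limit_cycle_init(
            model, 1.0, scales={"f": 0.0, "Na": 0.0}, equilibration_ms=30_000.0
        )
        assert init.quiescent


class TestTargetCalcium:
    def test_mock_constant_calcium_recovered_exactly(self):
        mock = MockConstantCalcium(c_const=2e-4)
        c_star = compute_target_calcium(mock, equilibration_ms=15_000.0)
        assert c_star == pytest.approx(2e-4, rel=1e-9)

    def test_reference_value_in_physiological_band(self, c_star):
        assert 5e-5 < c_star < 1e-3

    def test_consistent_on_resimulation(self, model, default_init, c_star):
        tr = run_fixed_n(model, 1.0, None, 10_000.0, default_init.state)
        cbar, _ = cycle_average_calcium(tr)
        assert cbar == pytest.approx(c_star, rel=0.01)

    def test_one_vs_three_cycle_average_agree(self, model, default_init):
        tr = run_fixed_n(model, 1.0, None, 10_000.0, default_init.state)
        ups = _upstroke_times_from_arrays(tr.time_ms, tr.voltage)
        assert ups.size >= 4

        def avg(t0, t1):
            mask = (tr.time_ms >= t0) & (tr.time_ms <= t1)
            return np.trapezoid(tr.calcium[mask], tr.time_ms[mask]) / (
                tr.time_ms[mask][-1] - tr.time_ms[mask][0]
            )

        one = avg(ups[0], ups[1])
        three = avg(ups[0], ups[3])
        assert one == pytest.approx(three, rel=0.005)


class TestTraceContainer:
    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            Trace(time_ms=np.arange(5.0), voltage=np.zeros(4))

    def test_non_increasing_time_rejected(self):
        with pytest.raises(InvalidParameterError):
            Trace(time_ms=np.array([0.0, 1.0, 1.0]), voltage=np.zeros(3))

    def test_unknown_protein_scale_rejected(self, model):
        with pytest.raises(InvalidParameterError):
            model.validate_scales({"Kv42": 1.2})
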