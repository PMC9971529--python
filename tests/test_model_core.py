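"""Unit tests for the single-bundle biophysics (parameters, P_o, drift)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otogrid import (
    BundleState,
    CellParams,
    ConfigurationError,
    InvalidInputError,
    ParameterSet,
    drift,
    motor_binding_probability,
    open_probability,
    single_motor_force,
)


class TestParameterSet:
    def test_derived_constants_from_published_values(self, params):
        # hand-derived from the printed constants
        assert params.D == pytest.approx(8.7e-9 / 0.14)
        assert params.D == pytest.approx(6.214e-8, rel=1e-3)
        assert params.A == pytest.approx(2.4056e7, rel=1e-3)
        assert params.delta == pytest.approx(4.4414e-9, rel=1e-3)

    def test_defaults_match_published_table(self, params):
        assert params.lambda_hb == 2.8e-6
        assert params.lambda_a == 10e-6
        assert params.K_gs == 750e-6
        assert params.K_sp == 600e-6
        assert params.K_es == 140e-6
        assert params.X_es == 20e-9
        assert params.tau == 0.1e-3
        assert params.tau_c == 1e-3
        assert params.C_M == 250e-3
        assert params.C0 == 0.0
        assert params.N == 50
        assert params.N_a == 3000
        assert params.T_a == pytest.approx(1.5 * params.T)
        assert params.p0 == 0.2

    def test_derived_constants_never_stale(self, params):
        doubled = params.with_(d_gs=2 * params.d_gs)
        assert doubled.D == pytest.approx(2 * params.D)
        assert doubled.delta == pytest.approx(params.delta / 2)

    @pytest.mark.parametrize(
        "field,value",
        [("lambda_hb", -1e-6), ("K_gs", 0.0), ("p0", 1.5), ("tau", np.nan)],
    )
    def test_invalid_parameters_rejected(self, params, field, value):
        with pytest.raises(ConfigurationError):
            params.with_(**{field: value})

    def test_c0_must_not_exceed_cm(self, params):
        with pytest.raises(ConfigurationError):
            params.with_(C0=1.0, C_M=0.5)


class TestCellParams:
    def test_p1_consistent_with_feedback_strength(self, params):
        cell = CellParams.from_feedback(a0=1.0, f_max=200e-12, S=1.5, params=params)
        assert cell.p1 == pytest.approx(-1.5 * params.p0 / params.C_M)

    def test_inconsistent_p1_rejected(self):
        with pytest.raises(ConfigurationError):
            CellParams(a0=1.0, f_max=1e-12, S=1.0, p1=+0.5)

    def test_nonpositive_a0_rejected(self, params):
        with pytest.raises(ConfigurationError):
            CellParams.from_feedback(a0=0.0, f_max=1e-12, S=1.0, params=params)


class TestOpenProbability:
    def test_saturates_at_extremes(self, params):
        assert open_probability(1.0, 0.0, params) == pytest.approx(1.0)
        assert open_probability(-1.0, 0.0, params) == pytest.approx(0.0)
        # no overflow warnings / NaN for huge separations
        assert np.isfinite(open_probability(1e6, 0.0, params))

    def test_half_open_at_algebraic_midpoint(self, params):
        x_mid = params.delta * np.log(params.A)
        assert open_probability(x_mid, 0.0, params) == pytest.approx(0.5, abs=1e-12)

    def test_rejects_nonfinite(self, params):
        with pytest.raises(InvalidInputError):
            open_probability(np.nan, 0.0, params)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        x=st.floats(-1e-6, 1e-6),
        dx=st.floats(1e-12, 1e-7),
    )
    def test_strictly_increasing_in_gating_extension(self, params, x, dx):
        lo = open_probability(x, 0.0, params)
        hi = open_probability(x + dx, 0.0, params)
        assert 0.0 < lo < 1.0 or lo in (0.0, 1.0)  # within fp range
        assert hi >= lo


class TestMotorForce:
    def test_printed_formula_value(self, params):
        cell = CellParams.from_feedback(a0=1.0, f_max=352e-12, S=1.0, params=params)
        f = single_motor_force(cell, params, mode="p0")
        assert f == pytest.approx(352e-12 / (3000 * 0.2))
        assert f == pytest.approx(5.87e-13, rel=1e-3)

    def test_zero_and_linear_scaling(self, params):
        zero = CellParams.from_feedback(a0=1.0, f_max=0.0, S=0.0, params=params)
        assert single_motor_force(zero, params) == 0.0
        one = CellParams.from_feedback(a0=1.0, f_max=100e-12, S=0.0, params=params)
        two = CellParams.from_feedback(a0=1.0, f_max=200e-12, S=0.0, params=params)
        for mode in ("ensemble", "p0"):
            assert single_motor_force(two, params, mode) == pytest.approx(
                2 * single_motor_force(one, params, mode)
            )

    def test_ensemble_mode_gives_fmax_stall_at_full_binding(self, params):
        cell = CellParams.from_feedback(a0=1.0, f_max=200e-12, S=0.0, params=params)
        f = single_motor_force(cell, params, mode="ensemble")
        assert params.gamma * params.N_a * f == pytest.approx(200e-12)


class TestBindingProbability:
    def test_resting_value(self, params):
        cell = CellParams.from_feedback(a0=1.0, f_max=1e-12, S=1.0, params=params)
        assert motor_binding_probability(0.0, cell, params) == pytest.approx(0.2)

    def test_zero_slope_is_constant(self, params):
        cell = CellParams.from_feedback(a0=1.0, f_max=1e-12, S=0.0, params=params)
        for C in (0.0, 0.1, params.C_M):
            assert motor_binding_probability(C, cell, params) == pytest.approx(params.p0)

    def test_saturating_feedback_identity(self, params):
        # p(C_M) = p0 (1 - S); S = 1 shuts binding off entirely
        cell = CellParams.from_feedback(a0=1.0, f_max=1e-12, S=1.0, params=params)
        assert motor_binding_probability(params.C_M, cell, params) == pytest.approx(0.0)
        cell2 = CellParams.from_feedback(a0=1.0, f_max=1e-12, S=0.5, params=params)
        assert motor_binding_probability(params.C_M, cell2, params) == pytest.approx(
            params.p0 * 0.5
        )

    def test_clamped_to_unit_interval(self, params):
        cell = CellParams.from_feedback(a0=1.0, f_max=1e-12, S=3.0, params=params)
        assert motor_binding_probability(params.C_M, cell, params) == 0.0
        raw = motor_binding_probability(params.C_M, cell, params, clamp=False)
        assert raw < 0.0


def _drift_oracle(X, Xa, C, F, a0, f_max, S, params, mode="ensemble"):
    """Independent transcription of the equations of motion (not shared
    with the implementation): returns (dX, dXa, dC)."""
    A = np.exp((params.DeltaG + params.K_gs * (params.d_gs / params.gamma) ** 2
                / (2 * params.N)) / (params.k_b * params.T))
    delta = params.N * params.k_b * params.T / (params.K_gs * (params.d_gs / params.gamma))
    D = params.d_gs / params.gamma
    Po = 1.0 / (1.0 + A * np.exp(-(X - Xa) / delta))
    p1 = -S * params.p0 / params.C_M
    p = min(max(params.p0 + p1 * C, 0.0), 1.0)
    if mode == "ensemble":
        stall = f_max * p
    else:
        stall = params.gamma * f_max * p / params.p0
    dX = (a0 / params.lambda_hb) * (
        -params.K_gs * (X - Xa - D * Po) - params.K_sp * X + F
    )
    dXa = (a0 / params.lambda_a) * (
        params.K_gs * (X - Xa - D * Po) - stall + params.K_es * (Xa + params.X_es)
    )
    dC = (a0 / params.tau) * (params.C0 - C + params.C_M * Po)
    return dX, dXa, dC


class TestDrift:
    def test_a0_rescales_all_three_rates(self, params):
        state = BundleState(X=5e-9, X_a=-60e-9, C=0.1)
        c1 = CellParams.from_feedback(a0=1.0, f_max=250e-12, S=1.0, params=params)
        c3 = CellParams.from_feedback(a0=3.0, f_max=250e-12, S=1.0, params=params)
        d1 = drift(state, 0.0, c1, params)
        d3 = drift(state, 0.0, c3, params)
        for a, b in zip(d1, d3):
            assert b == pytest.approx(3 * a, rel=1e-12)

    def test_position_rate_vanishes_when_forces_balance(self, params):
        # X = 0 and X_a chosen so the gating-spring term is zero
        X = 0.0
        # solve X - Xa - D*Po(X-Xa) = 0 by bisection on y = X - Xa
        lo, hi = -1e-7, 1e-7
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            val = mid - params.D * open_probability(mid, 0.0, params)
            if val > 0:
                hi = mid
            else:
                lo = mid
        Xa = X - 0.5 * (lo + hi)
        cell = CellParams.from_feedback(a0=1.0, f_max=0.0, S=0.0, params=params)
        dX, _, _ = drift(BundleState(X=X, X_a=Xa, C=0.0), 0.0, cell, params)
        assert abs(dX) < 1e-6  # m/s, vs typical scales of 1e-2

    def test_agrees_with_independent_transcription(self, params):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            X = rng.uniform(-2e-7, 2e-7)
            Xa = rng.uniform(-3e-7, 2e-7)
            C = rng.uniform(0.0, params.C_M)
            F = rng.uniform(-5e-11, 5e-11)
            a0 = rng.uniform(0.5, 2.5)
            f_max = rng.uniform(0.0, 352e-12)
            S = rng.uniform(0.0, 3.0)
            for mode in ("ensemble", "p0"):
                cell = CellParams.from_feedback(a0=a0, f_max=f_max, S=S, params=params)
                got = drift(BundleState(X=X, X_a=Xa, C=C), F, cell, params, motor_mode=mode)
                want = _drift_oracle(X, Xa, C, F, a0, f_max, S, params, mode)
                for g, w in zip(got, want):
                    assert g == pytest.approx(w, rel=1e-12, abs=1e-30)

    def test_nonfinite_state_rejected_with_component_name(self, params):
        cell = CellParams.from_feedback(a0=1.0, f_max=1e-12, S=1.0, params=params)
        with pytest.raises(InvalidInputError, match="X_a"):
            drift(BundleState(X=0.0, X_a=np.inf, C=0.0), 0.0, cell, params)
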