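"""Architecture models: activation functions, ODEs, steady-state solvers."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sigspec as sg
from sigspec.models import (ConvergenceError, InputCondition, ParameterError,
                            network_from_dict, network_to_dict, rhs)
from tests.conftest import make_random_network

X_ON, Y_ON = InputCondition.X_ON, InputCondition.Y_ON


class TestActivation:
    @pytest.mark.parametrize("n, eps, u, expected", [
        (3.0, 1.0, 1.0, 0.5),          # half-max at threshold
        (2.0, 0.7, 0.0, 0.0),          # zero input
        (1.0, 2.0, 18.0, 0.9),         # u = eps*p/(1-p) with p = 0.9
        (2.0, 1.0, 3.0, 0.9),          # 9/(9+1)
    ])
    def test_hill_values(self, n, eps, u, expected):
        assert sg.evaluate_activation(sg.hill(n, eps), u) == pytest.approx(expected)

    def test_linear_is_identity(self):
        assert sg.evaluate_activation(sg.linear(), 3.25) == 3.25

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            sg.evaluate_activation(sg.hill(2.0), -0.1)

    @given(st.floats(1.0, 10.0), st.floats(0.01, 10.0),
           st.floats(0.0, 50.0), st.floats(0.0, 50.0))
    def test_hill_monotone_and_bounded(self, n, eps, u1, u2):
        f = sg.hill(n, eps)
        lo, hi = sorted((u1, u2))
        assert 0.0 <= f(lo) <= f(hi) < 1.0


class TestParameters:
    def test_mechanism_fields_enforced(self):
        with pytest.raises(ParameterError, match="eps_g"):
            sg.NetworkParameters("cpi", 1, 1, 1, 1, 1, 1, 1, 1)
        with pytest.raises(ParameterError):
            sg.NetworkParameters("basic", 1, 1, 1, 1, 1, 1, 1, 1, eps_g=1.0)

    def test_basic_requires_single_d1(self):
        with pytest.raises(ParameterError, match="single d1"):
            sg.NetworkParameters("basic", 1, 1, 1, 1, 1.0, 2.0, 1, 1)

    def test_connection_strengths(self):
        p = sg.NetworkParameters.basic(a2=2.0, d2x=4.0, b2=3.0, d2y=1.5)
        assert p.alpha == 0.5
        assert p.beta == 2.0

    def test_config_round_trip(self, rng):
        for mech in ("basic", "cpi", "cs", "sc"):
            p = make_random_network(rng, mech)
            assert network_from_dict(network_to_dict(p)) == p

    def test_config_unknown_field_named(self):
        with pytest.raises(ParameterError, match="bogus"):
            network_from_dict({"mechanism": "basic", "a1": 1, "b1": 1,
                               "a2": 1, "b2": 1, "bogus": 3})


class TestRHS:
    def test_empty_system_is_stationary(self):
        p = sg.NetworkParameters.basic(x0=0.0, y0=0.0)
        assert np.allclose(rhs(p, [0.0, 0.0, 0.0]), 0.0)

    def test_x1_fixed_point_component(self):
        p = sg.NetworkParameters.basic(a1=1.0, d1=1.0, x0=1.0, y0=1.0)
        assert rhs(p, [1.0, 0.0, 0.0], X_ON)[0] == 0.0

    def test_cpi_halves_y2_production_at_ic50(self):
        cpi = sg.NetworkParameters.cpi(eps_g=0.7)
        basic = sg.NetworkParameters.basic()
        state = [1.3, 0.7, 0.0]  # x2 exactly at the IC50
        assert rhs(cpi, state, X_ON)[2] == pytest.approx(
            0.5 * rhs(basic, state, X_ON)[2])

    def test_dimension_mismatch_rejected(self):
        p = sg.NetworkParameters.sc(D_in=1.0, D_out=1.0)
        with pytest.raises(ValueError, match="dimension"):
            rhs(p, [0.0, 0.0, 0.0])

    def test_analytic_state_zeroes_rhs(self, rng):
        for mech in ("basic", "cpi", "cs", "sc"):
            p = make_random_network(rng, mech)
            for cond in (X_ON, Y_ON):
                st_ = sg.solve_steady_state_analytic(p, cond)
                resid = rhs(p, st_.state_vector(), cond)
                assert np.max(np.abs(resid)) < 1e-12 * (1 + np.max(st_.state_vector()))


class TestSteadyState:
    def test_basic_closed_form(self):
        p = sg.NetworkParameters.basic(a1=1.0, a2=2.0, b2=1.0)
        st_ = sg.solve_steady_state_analytic(p, X_ON)
        assert (st_.x1, st_.x2, st_.y2) == (1.0, 2.0, 1.0)

    def test_sc_pool_ratio_is_one_plus_d1_over_d(self):
        p = sg.NetworkParameters.sc(D_in=1.0, D_out=1.0)  # d1 = D = 1
        st_ = sg.solve_steady_state_analytic(p, X_ON)
        assert st_.x1n / st_.x1c == pytest.approx(2.0)

    def test_cs_closed_leak_kills_x_output(self):
        p = sg.NetworkParameters.cs(k_leak=0.0)
        assert sg.solve_steady_state_analytic(p, Y_ON).x2 == 0.0

    def test_cpi_wide_ic50_recovers_basic(self):
        cpi = sg.NetworkParameters.cpi(eps_g=1e12)
        basic = sg.NetworkParameters.basic()
        for cond in (X_ON, Y_ON):
            a = sg.solve_steady_state_analytic(cpi, cond)
            b = sg.solve_steady_state_analytic(basic, cond)
            assert a.y2 == pytest.approx(b.y2, rel=1e-9)

    def test_sc_no_exchange_decouples(self):
        p = sg.NetworkParameters.sc(D_in=0.0, D_out=0.0)
        st_ = sg.solve_steady_state_numeric(p, X_ON)
        assert st_.x1c == pytest.approx(0.0, abs=1e-12)
        assert st_.y2 == pytest.approx(0.0, abs=1e-12)

    def test_numeric_matches_analytic(self, rng):
        for i in range(24):
            mech = ("basic", "cpi", "cs", "sc")[i % 4]
            act = ("linear", "hill")[i % 2]
            p = make_random_network(rng, mech, act)
            cond = (X_ON, Y_ON)[(i // 2) % 2]
            a = sg.solve_steady_state_analytic(p, cond).state_vector()
            n = sg.solve_steady_state_numeric(p, cond).state_vector()
            assert np.all(np.abs(a - n) <= 1e-6 * np.abs(a) + 1e-12)

    def test_nonconvergence_is_explicit(self):
        p = sg.NetworkParameters.basic()
        with pytest.raises(ConvergenceError):
            sg.solve_steady_state_numeric(p, X_ON, t_max=1e-4)

    def test_basic_monotone_in_input(self):
        from dataclasses import replace
        levels = [0.5, 1.0, 2.0, 5.0]
        p = sg.NetworkParameters.basic(fX=sg.hill(3, 1.2), fY=sg.hill(2, 0.6))
        states = [sg.solve_steady_state_analytic(replace(p, x0=lv), X_ON)
                  for lv in levels]
        for a, b in zip(states, states[1:]):
            assert a.x1 <= b.x1 and a.x2 <= b.x2 and a.y2 <= b.y2


class TestQuartet:
    def test_symmetric_branches(self):
        p = sg.NetworkParameters.basic(a1=1, b1=1, a2=2, b2=2)
        q = sg.output_quartet(p)
        assert q.x_given_x == q.y_given_x
        assert q.x_given_y == q.y_given_y

    def test_equal_inputs_give_equal_x_outputs(self):
        p = sg.NetworkParameters.basic(a1=1.5, b1=1.5, x0=2.0, y0=2.0)
        q = sg.output_quartet(p)
        assert q.x_given_x == q.x_given_y

    def test_cs_closed_leak_quartet(self):
        q = sg.output_quartet(sg.NetworkParameters.cs(k_leak=0.0))
        assert q.x_given_y == 0.0

    def test_requires_positive_inputs(self):
        p = sg.NetworkParameters.basic(x0=0.0)
        with pytest.raises(ParameterError):
            sg.output_quartet(p)

    def test_nonnegative_finite(self, rng):
        for mech in ("basic", "cpi", "cs", "sc"):
            q = sg.output_quartet(make_random_network(rng, mech))
            assert all(v >= 0 and math.isfinite(v) for v in q.as_tuple())


class TestComparativeInvariants:
    """Insulating mechanisms act only on the outputs they are wired to."""

    def test_cpi_reduces_only_y_outputs(self, rng):
        for _ in range(20):
            cpi = make_random_network(rng, "cpi")
            basic = sg.NetworkParameters.basic(
                a1=cpi.a1, b1=cpi.b1, a2=cpi.a2, b2=cpi.b2, d1=cpi.d1,
                d2x=cpi.d2x, d2y=cpi.d2y, fX=cpi.fX, fY=cpi.fY,
                x0=cpi.x0, y0=cpi.y0)
            qc, qb = sg.output_quartet(cpi), sg.output_quartet(basic)
            assert qc.x_given_x == qb.x_given_x and qc.x_given_y == qb.x_given_y
            assert qc.y_given_x <= qb.y_given_x and qc.y_given_y <= qb.y_given_y

    def test_cs_scales_only_crosstalk_by_k_leak(self, rng):
        for _ in range(20):
            cs = make_random_network(rng, "cs")
            basic = sg.NetworkParameters.basic(
                a1=cs.a1, b1=cs.b1, a2=cs.a2, b2=cs.b2, d1=cs.d1,
                d2x=cs.d2x, d2y=cs.d2y, fX=cs.fX, fY=cs.fY, x0=cs.x0, y0=cs.y0)
            qc, qb = sg.output_quartet(cs), sg.output_quartet(basic)
            assert qc.x_given_y == pytest.approx(cs.k_leak * qb.x_given_y, rel=1e-12)
            assert qc.x_given_x == qb.x_given_x
            assert qc.y_given_x == qb.y_given_x and qc.y_given_y == qb.y_given_y
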