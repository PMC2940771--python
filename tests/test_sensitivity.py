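"""Derivative-sign analysis for the Hill exponents and mutual-benefit tests."""

import numpy as np
import pytest

import sigspec as sg
from sigspec.sensitivity import (derivative_signs, mutual_benefit_feasible,
                                 mutual_benefit_feasible_from_params,
                                 shared_pool_states,
                                 threshold_sign_predictions)
from tests.conftest import make_random_network


class TestDerivativeSigns:
    def test_basic_above_threshold_favors_n(self):
        # x1|X = 3 > eps_X = 1 -> raising n improves S_X
        p = sg.NetworkParameters.basic(a1=3.0, b1=0.5,
                                       fX=sg.hill(2, 1.0), fY=sg.hill(2, 0.3))
        assert derivative_signs(p).d_sx_dn == "positive"

    def test_exactly_at_threshold_is_zero(self):
        # x1|X = 1 = eps_X: S_X is stationary in n
        p = sg.NetworkParameters.basic(a1=1.0, b1=0.5,
                                       fX=sg.hill(2, 1.0), fY=sg.hill(2, 0.3))
        assert derivative_signs(p).d_sx_dn == "zero"

    def test_sc_symmetric_both_exponents_favorable(self):
        net = sg.sc_symmetric_network(2.0, 1.0, 2.0)
        pools = shared_pool_states(net)
        assert pools["x1n_x"] == pytest.approx(4 / 3)
        assert pools["x1n_y"] == pytest.approx(2 / 3)
        rep = derivative_signs(net)
        assert rep.d_sx_dn == "positive"
        assert rep.d_sy_dn == "positive"
        assert rep.conditions_satisfiable

    def test_linear_activation_rejected(self):
        with pytest.raises(ValueError):
            derivative_signs(sg.NetworkParameters.basic())

    @pytest.mark.parametrize("mechanism", ["basic", "cpi", "cs", "sc"])
    def test_finite_differences_match_threshold_conditions(self, mechanism, rng):
        """Measured specificity-derivative signs agree with the closed-form
        threshold conditions on the shared component's steady states."""
        checked = 0
        for _ in range(15):
            p = make_random_network(rng, mechanism, "hill", max_exponent=3.0)
            rep = derivative_signs(p)
            pred = threshold_sign_predictions(p)
            for key, want in pred.items():
                got = getattr(rep, key)
                if want != "zero" and got != "zero":
                    assert got == want, (mechanism, key, p)
                    checked += 1
        assert checked > 20


class TestStrategyRegimes:
    def _cpi_favorable(self, rng):
        # eps_Y < x1|Y < eps_X < x1|X
        x1y = float(rng.uniform(0.3, 0.8))
        x1x = float(rng.uniform(1.5, 4.0))
        eps_y = float(rng.uniform(0.05, 0.9)) * x1y
        return sg.NetworkParameters.cpi(
            eps_g=float(rng.uniform(0.05, 1.0)), a1=x1x, b1=x1y,
            a2=float(rng.uniform(0.5, 2.0)), b2=float(rng.uniform(0.5, 2.0)),
            fX=sg.hill(2.5, 1.0), fY=sg.hill(2.5, eps_y))

    def test_cpi_n_favorable_m_mixed(self, rng):
        """In the CPI operating regime raising n helps every indicator while
        raising m trades S_Y against S_X."""
        for _ in range(10):
            rep = derivative_signs(self._cpi_favorable(rng))
            assert rep.d_sx_dn == "positive"
            assert rep.d_sy_dn == "positive"
            assert rep.d_fx_dn == "positive"
            assert rep.d_fy_dn == "positive"
            assert rep.d_sx_dm == "negative"
            assert rep.d_sy_dm == "positive"
            assert not rep.conditions_satisfiable

    def test_cs_m_favorable_n_costs_sy(self, rng):
        # eps_X < x1|X < eps_Y < x1|Y
        for _ in range(10):
            x1x = float(rng.uniform(1.2, 2.0))
            x1y = float(rng.uniform(3.0, 6.0))
            eps_y = float(rng.uniform(1.05, 1.4)) * x1x
            p = sg.NetworkParameters.cs(
                k_leak=float(rng.uniform(0.05, 0.5)), a1=x1x, b1=x1y,
                fX=sg.hill(2.5, 1.0), fY=sg.hill(2.5, eps_y))
            rep = derivative_signs(p)
            assert rep.d_sy_dm == "positive"
            assert rep.d_sx_dm == "positive"  # x1|X < eps_Y
            assert rep.d_sy_dn == "negative"  # x1|Y > eps_X
            assert not rep.conditions_satisfiable

    def test_sc_feasible_mfms_nondecreasing_in_both(self):
        """When both pool intervals hold, raising either exponent does not
        hurt the sc network's MFMS."""
        net = sg.sc_symmetric_network(2.0, 4.0, 2.0)
        assert mutual_benefit_feasible_from_params(net)[0]
        base = sg.specificity_indicators(sg.output_quartet(net)).mfms
        for dn, dm in ((0.5, 0.0), (0.0, 0.5), (0.5, 0.5)):
            bumped = net.with_exponents(2.0 + dn, 2.0 + dm)
            val = sg.specificity_indicators(sg.output_quartet(bumped)).mfms
            assert val >= base - 1e-12


class TestMutualBenefitFeasibility:
    @pytest.mark.parametrize("mechanism", ["basic", "cpi", "cs"])
    def test_single_pool_always_infeasible(self, mechanism, rng):
        p = make_random_network(rng, mechanism, "hill")
        feasible, witness = mutual_benefit_feasible_from_params(p)
        assert not feasible
        assert "cyclically" in witness["reason"]

    def test_sc_interval_witness(self):
        pools = {"x1n_x": 4 / 3, "x1n_y": 2 / 3, "x1c_x": 2 / 3, "x1c_y": 4 / 3}
        feasible, witness = mutual_benefit_feasible("sc", pools, 1.0, 1.0)
        assert feasible
        assert witness["anchored_interval"]["holds"]
        assert witness["cytosolic_interval"]["holds"]

    def test_sc_fast_exchange_collapses_intervals(self):
        # D -> infinity equalizes the pools; thresholds cannot separate them
        net = sg.NetworkParameters.sc(D_in=1e9, D_out=1e9, a1=2.0, b1=2.0,
                                      fX=sg.hill(2, 1.0), fY=sg.hill(2, 1.0))
        assert not mutual_benefit_feasible_from_params(net)[0]
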