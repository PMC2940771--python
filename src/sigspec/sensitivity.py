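"""When does raising a Hill exponent help? Derivative-sign analysis.

Treating the Hill exponents n (X branch) and m (Y branch) as continuous,
the sign of each indicator's partial derivative tells whether more
ultrasensitivity in a branch improves that indicator.  For the single-pool
architectures the specificity signs reduce to threshold conditions on the
shared component's steady states:

    dS_X/dn > 0  iff  x1|X > eps_X        dS_Y/dn > 0  iff  x1|Y < eps_X
    dS_X/dm > 0  iff  x1|X < eps_Y        dS_Y/dm > 0  iff  x1|Y > eps_Y

For all four S-derivatives to be positive these would have to chain into
x1|X < eps_Y < x1|Y < eps_X < x1|X, which is cyclic and unsatisfiable —
single-pool networks can only point ultrasensitivity at one crosstalk term.
Scaffolding/compartmentalization splits the shared component into two pools,
the conditions decouple into two genuine intervals

    x1n|Y < eps_X < x1n|X    and    x1c|X < eps_Y < x1c|Y

and both exponents can be raised to mutual benefit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .metrics import specificity_indicators
from .models import (InputCondition, NetworkParameters, output_quartet,
                     solve_steady_state_analytic)

__all__ = [
    "DerivativeSignReport",
    "derivative_signs",
    "mutual_benefit_feasible",
    "mutual_benefit_feasible_from_params",
    "shared_pool_states",
    "threshold_sign_predictions",
]

_INDICATORS = ("s_x", "s_y", "f_x", "f_y")


@dataclass(frozen=True)
class DerivativeSignReport:
    """Signs of the eight indicator partial derivatives w.r.t. n and m.

    Each field is ``"positive"``, ``"negative"`` or ``"zero"`` (zero meaning
    below numerical resolution).  ``conditions_satisfiable`` reports whether
    the mechanism admits simultaneous benefit from raising both exponents.
    """

    mechanism: str
    d_sx_dn: str
    d_sy_dn: str
    d_sx_dm: str
    d_sy_dm: str
    d_fx_dn: str
    d_fy_dn: str
    d_fx_dm: str
    d_fy_dm: str
    conditions_satisfiable: bool

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def shared_pool_states(params: NetworkParameters) -> dict:
    """Steady-state shared-component levels under each exclusive input.

    Single-pool architectures return ``x1_x``/``x1_y``; sc returns the four
    pool values ``x1n_x``, ``x1n_y``, ``x1c_x``, ``x1c_y`` (suffix = input).
    """
    on_x = solve_steady_state_analytic(params, InputCondition.X_ON)
    on_y = solve_steady_state_analytic(params, InputCondition.Y_ON)
    if params.mechanism == "sc":
        return {"x1n_x": on_x.x1n, "x1n_y": on_y.x1n,
                "x1c_x": on_x.x1c, "x1c_y": on_y.x1c}
    return {"x1_x": on_x.x1, "x1_y": on_y.x1}


def _indicator_values(params: NetworkParameters, n: float, m: float) -> dict:
    q = output_quartet(params.with_exponents(n, m))
    ind = specificity_indicators(q)
    return {k: getattr(ind, k) for k in _INDICATORS}


def _classify(deriv: float, scale: float, zero_tol: float) -> str:
    if abs(deriv) <= zero_tol * max(1.0, scale):
        return "zero"
    return "positive" if deriv > 0 else "negative"


def derivative_signs(params: NetworkParameters,
                     rel_step: float = 1e-4,
                     zero_tol: float = 1e-7) -> DerivativeSignReport:
    """Signs of d(indicator)/dn and d(indicator)/dm by central differences.

    Both activation branches must be Hill.  The step is proportional to the
    exponent (floored at ``rel_step``) and each sign is confirmed under step
    halving; a derivative whose magnitude stays below resolution at both
    steps is reported as ``"zero"``.
    """
    if params.fX.kind != "hill" or params.fY.kind != "hill":
        raise ValueError("derivative analysis requires Hill activation on both branches")
    n0, m0 = params.fX.exponent, params.fY.exponent
    base = _indicator_values(params, n0, m0)

    def central(wrt: str, h: float) -> dict:
        if wrt == "n":
            hi = _indicator_values(params, n0 + h, m0)
            lo = _indicator_values(params, max(n0 - h, 1.0), m0)
            span = (n0 + h) - max(n0 - h, 1.0)
        else:
            hi = _indicator_values(params, n0, m0 + h)
            lo = _indicator_values(params, n0, max(m0 - h, 1.0))
            span = (m0 + h) - max(m0 - h, 1.0)
        return {k: (hi[k] - lo[k]) / span for k in _INDICATORS}

    signs: dict[str, str] = {}
    for wrt, x0 in (("n", n0), ("m", m0)):
        h = max(rel_step, rel_step * x0)
        d1 = central(wrt, h)
        d2 = central(wrt, h / 2.0)
        for k in _INDICATORS:
            scale = abs(base[k]) if math.isfinite(base[k]) else 1.0
            s1 = _classify(d1[k], scale, zero_tol)
            s2 = _classify(d2[k], scale, zero_tol)
            # prefer the finer step when halving disagrees
            signs[f"d_{k.replace('_', '')}_d{wrt}"] = s2 if s1 != s2 else s1

    feasible, _ = mutual_benefit_feasible_from_params(params)
    return DerivativeSignReport(mechanism=params.mechanism,
                                conditions_satisfiable=feasible, **signs)


def threshold_sign_predictions(params: NetworkParameters) -> dict:
    """Predicted S-derivative signs from the steady-state threshold conditions.

    Applies the single-pool conditions (x1 vs eps) for basic/cpi/cs and the
    pool-specific conditions (x1n, x1c vs eps) for sc.  Only the four
    specificity derivatives have clean threshold forms; fidelity derivative
    signs depend on both steady states jointly.
    """
    eps_x, eps_y = params.fX.threshold, params.fY.threshold
    pools = shared_pool_states(params)
    if params.mechanism == "sc":
        ux, uy = pools["x1n_x"], pools["x1n_y"]   # drive fX
        vx, vy = pools["x1c_x"], pools["x1c_y"]   # drive fY
    else:
        ux, uy = pools["x1_x"], pools["x1_y"]
        vx, vy = ux, uy

    def sign(cond_gt: float, ref: float, positive_if_greater: bool) -> str:
        if cond_gt == ref:
            return "zero"
        return "positive" if (cond_gt > ref) == positive_if_greater else "negative"

    return {
        "d_sx_dn": sign(ux, eps_x, True),
        "d_sy_dn": sign(uy, eps_x, False),
        "d_sx_dm": sign(vx, eps_y, False),
        "d_sy_dm": sign(vy, eps_y, True),
    }


def mutual_benefit_feasible(mechanism: str, pools: dict,
                            eps_x: float, eps_y: float) -> tuple[bool, dict]:
    """Can raising both exponents improve all indicators simultaneously?

    For basic/cpi/cs the combined threshold conditions form the cyclic chain
    x1|X < eps_Y < x1|Y < eps_X < x1|X, which no steady state satisfies:
    always infeasible.  For sc, feasible exactly when both pool intervals
    x1n|Y < eps_X < x1n|X and x1c|X < eps_Y < x1c|Y hold; the witness
    reports each interval and whether it holds.
    """
    if mechanism != "sc":
        return False, {
            "reason": "single shared pool: the threshold conditions chain "
                      "cyclically (x1|X < eps_Y < x1|Y < eps_X < x1|X) and "
                      "cannot all hold",
        }
    iv_n = (pools["x1n_y"], eps_x, pools["x1n_x"])
    iv_c = (pools["x1c_x"], eps_y, pools["x1c_y"])
    ok_n = iv_n[0] < iv_n[1] < iv_n[2]
    ok_c = iv_c[0] < iv_c[1] < iv_c[2]
    witness = {
        "anchored_interval": {"lower": iv_n[0], "eps_X": eps_x,
                              "upper": iv_n[2], "holds": ok_n},
        "cytosolic_interval": {"lower": iv_c[0], "eps_Y": eps_y,
                               "upper": iv_c[2], "holds": ok_c},
    }
    return ok_n and ok_c, witness


def mutual_benefit_feasible_from_params(params: NetworkParameters) -> tuple[bool, dict]:
    """Feasibility check using the parameter set's own steady states/thresholds."""
    pools = shared_pool_states(params)
    return mutual_benefit_feasible(params.mechanism, pools,
                                   params.fX.threshold, params.fY.threshold)
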