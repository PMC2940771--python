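"""Steady-state models of two signaling pathways sharing an intermediate component.

The network couples an X pathway (input ``x0``, output ``x2``) and a Y pathway
(input ``y0``, output ``y2``) through a shared intermediate ``x1``.  Four
architectures are supported:

``basic``
    No insulating mechanism: ``x1`` integrates both inputs and drives both
    outputs through activation functions ``fX``/``fY``.
``cpi``
    Cross-pathway inhibition: production of ``y2`` is inhibited by ``x2``
    with IC50 ``eps_g``.
``cs``
    Combinatorial signaling: production of ``x2`` requires a coincident
    third input, modeled as a multiplicative gate equal to 1 under X input
    and ``k_leak`` under Y input.
``sc``
    Scaffolding/compartmentalization: the shared component exists in two
    exchanging pools, scaffold-anchored ``x1n`` (drives ``x2``) and cytosolic
    ``x1c`` (drives ``y2``), with exchange rates ``D_in``/``D_out``.

Activation is linear (weakly-activated pathways) or a Hill function with
exponent ``n``/``m`` and threshold ``eps_X``/``eps_Y``; Hill exponents above 1
model ultrasensitive (switch-like) responses.

All architectures admit closed-form steady states; a stiff ODE integrator is
provided as an independent numerical route to the same fixed points.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "ActivationFunction",
    "ConvergenceError",
    "InputCondition",
    "NetworkParameters",
    "OutputQuartet",
    "ParameterError",
    "SteadyState",
    "evaluate_activation",
    "hill",
    "linear",
    "load_network",
    "network_from_dict",
    "network_to_dict",
    "output_quartet",
    "rhs",
    "save_network",
    "solve_steady_state_analytic",
    "solve_steady_state_numeric",
]


class ParameterError(ValueError):
    """Invalid or inconsistent network parameters."""


class ConvergenceError(RuntimeError):
    """The numerical integrator failed to reach a steady state within t_max."""


# ---------------------------------------------------------------------------
# activation functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivationFunction:
    """Monotone activation of a pathway output by the shared component.

    kind
        ``"linear"`` — identity, f(u) = u (weak activation);
        ``"hill"`` — f(u) = u^n / (u^n + eps^n), half-maximal at ``threshold``;
        ``"custom"`` — arbitrary monotone non-decreasing callable ``func``.
    exponent
        Hill exponent (n or m), >= 1.  1 is hyperbolic/Michaelian; larger
        values are increasingly switch-like (ultrasensitive).
    threshold
        Hill threshold concentration (eps_X or eps_Y), > 0.
    """

    kind: str = "hill"
    exponent: float = 1.0
    threshold: float = 1.0
    func: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "hill", "custom"):
            raise ParameterError(f"unknown activation kind {self.kind!r}")
        if self.kind == "hill":
            if self.exponent < 1:
                raise ParameterError("Hill exponent must be >= 1")
            if self.threshold <= 0:
                raise ParameterError("Hill threshold must be > 0")
        if self.kind == "custom" and self.func is None:
            raise ParameterError("custom activation requires a callable")

    def __call__(self, u: float) -> float:
        return evaluate_activation(self, u)


def linear() -> ActivationFunction:
    """Identity activation for a weakly-activated pathway."""
    return ActivationFunction(kind="linear")


def hill(exponent: float, threshold: float = 1.0) -> ActivationFunction:
    """Hill activation with the given exponent and half-max threshold."""
    return ActivationFunction(kind="hill", exponent=exponent, threshold=threshold)


def evaluate_activation(f: ActivationFunction, u: float) -> float:
    """Evaluate an activation function at concentration ``u`` >= 0.

    Hill values lie in [0, 1): 0 at u=0, exactly 0.5 at the threshold.
    Linear returns ``u`` itself.
    """
    u = float(u)
    if u < 0 or not math.isfinite(u):
        raise ValueError(f"activation input must be finite and >= 0, got {u}")
    if f.kind == "linear":
        return u
    if f.kind == "custom":
        return float(f.func(u))  # type: ignore[misc]
    if u == 0.0:
        return 0.0
    # (u/eps)^n form avoids overflow for large u and keeps f in [0, 1]
    r = (u / f.threshold) ** f.exponent
    if math.isinf(r):
        return 1.0
    return r / (r + 1.0)


# ---------------------------------------------------------------------------
# network parameters
# ---------------------------------------------------------------------------


class InputCondition(enum.Enum):
    """Which exclusive input is applied: X_ON (x0 > 0, y0 = 0) or Y_ON."""

    X_ON = "X_on"
    Y_ON = "Y_on"


MECHANISMS = ("basic", "cpi", "cs", "sc")


@dataclass(frozen=True)
class NetworkParameters:
    """Full parameterization of one two-pathway network instance.

    ``a1``/``b1`` are the activation rate coefficients of the shared component
    by the X and Y inputs; ``a2``/``b2`` those of the outputs; ``d*`` are decay
    rate constants.  The connection strengths alpha = a2/d2x and beta = b2/d2y
    measure how strongly the shared component drives each output.

    Mechanism-specific fields are required exactly when the mechanism uses
    them: ``eps_g`` (cpi), ``k_leak`` (cs), ``D_in``/``D_out`` (sc).  The
    non-sc architectures use a single shared-component decay rate
    (``d1x == d1y``), exposed as ``d1``.
    """

    mechanism: str
    a1: float
    b1: float
    a2: float
    b2: float
    d1x: float
    d1y: float
    d2x: float
    d2y: float
    fX: ActivationFunction = field(default_factory=linear)
    fY: ActivationFunction = field(default_factory=linear)
    x0: float = 1.0
    y0: float = 1.0
    eps_g: float | None = None
    k_leak: float | None = None
    D_in: float | None = None
    D_out: float | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ParameterError(f"unknown mechanism {self.mechanism!r}")
        for name in ("a1", "b1", "a2", "b2", "d1x", "d1y", "d2x", "d2y"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ParameterError(f"rate constant {name} must be > 0, got {v}")
        for name in ("x0", "y0"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ParameterError(f"input level {name} must be >= 0, got {v}")
        if self.mechanism != "sc" and self.d1x != self.d1y:
            raise ParameterError(
                f"{self.mechanism} architecture uses a single d1 (d1x must equal d1y)"
            )
        if self.mechanism == "cpi":
            if self.eps_g is None or self.eps_g <= 0:
                raise ParameterError("cpi requires eps_g > 0 (IC50 of cross-inhibition)")
        elif self.eps_g is not None:
            raise ParameterError("eps_g is only meaningful for the cpi mechanism")
        if self.mechanism == "cs":
            if self.k_leak is None or not 0 <= self.k_leak <= 1:
                raise ParameterError("cs requires k_leak in [0, 1]")
        elif self.k_leak is not None:
            raise ParameterError("k_leak is only meaningful for the cs mechanism")
        if self.mechanism == "sc":
            if self.D_in is None or self.D_out is None or self.D_in < 0 or self.D_out < 0:
                raise ParameterError("sc requires exchange rates D_in, D_out >= 0")
        elif self.D_in is not None or self.D_out is not None:
            raise ParameterError("D_in/D_out are only meaningful for the sc mechanism")

    @property
    def d1(self) -> float:
        """Shared-component decay rate for the single-pool architectures."""
        if self.mechanism == "sc" and self.d1x != self.d1y:
            raise ParameterError("sc network with d1x != d1y has no single d1")
        return self.d1x

    @property
    def alpha(self) -> float:
        """Connection strength from the shared component to the X output."""
        return self.a2 / self.d2x

    @property
    def beta(self) -> float:
        """Connection strength from the shared component to the Y output."""
        return self.b2 / self.d2y

    @property
    def state_dim(self) -> int:
        return 4 if self.mechanism == "sc" else 3

    # convenience constructors ------------------------------------------------

    @classmethod
    def basic(cls, *, a1=1.0, b1=1.0, a2=1.0, b2=1.0, d1=1.0, d2x=1.0, d2y=1.0,
              fX=None, fY=None, x0=1.0, y0=1.0) -> "NetworkParameters":
        return cls("basic", a1, b1, a2, b2, d1, d1, d2x, d2y,
                   fX or linear(), fY or linear(), x0, y0)

    @classmethod
    def cpi(cls, *, eps_g, a1=1.0, b1=1.0, a2=1.0, b2=1.0, d1=1.0, d2x=1.0,
            d2y=1.0, fX=None, fY=None, x0=1.0, y0=1.0) -> "NetworkParameters":
        return cls("cpi", a1, b1, a2, b2, d1, d1, d2x, d2y,
                   fX or linear(), fY or linear(), x0, y0, eps_g=eps_g)

    @classmethod
    def cs(cls, *, k_leak, a1=1.0, b1=1.0, a2=1.0, b2=1.0, d1=1.0, d2x=1.0,
           d2y=1.0, fX=None, fY=None, x0=1.0, y0=1.0) -> "NetworkParameters":
        return cls("cs", a1, b1, a2, b2, d1, d1, d2x, d2y,
                   fX or linear(), fY or linear(), x0, y0, k_leak=k_leak)

    @classmethod
    def sc(cls, *, D_in, D_out, a1=1.0, b1=1.0, a2=1.0, b2=1.0, d1x=1.0,
           d1y=1.0, d2x=1.0, d2y=1.0, fX=None, fY=None, x0=1.0,
           y0=1.0) -> "NetworkParameters":
        return cls("sc", a1, b1, a2, b2, d1x, d1y, d2x, d2y,
                   fX or linear(), fY or linear(), x0, y0,
                   D_in=D_in, D_out=D_out)

    def with_exponents(self, n: float | None = None, m: float | None = None) -> "NetworkParameters":
        """Copy with replaced Hill exponents on the X (n) and/or Y (m) branch."""
        fX = replace(self.fX, exponent=float(n)) if n is not None else self.fX
        fY = replace(self.fY, exponent=float(m)) if m is not None else self.fY
        return replace(self, fX=fX, fY=fY)


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteadyState:
    """Resolved steady state under one exclusive input condition.

    Single-pool architectures populate ``x1``; the sc architecture populates
    the scaffold-anchored ``x1n`` and cytosolic ``x1c`` pools instead.
    """

    x2: float
    y2: float
    condition: InputCondition
    x1: float | None = None
    x1n: float | None = None
    x1c: float | None = None

    def state_vector(self) -> np.ndarray:
        if self.x1 is not None:
            return np.array([self.x1, self.x2, self.y2])
        return np.array([self.x1n, self.x1c, self.x2, self.y2])


@dataclass(frozen=True)
class OutputQuartet:
    """The four steady-state outputs: X|X, X|Y, Y|X, Y|Y.

    ``x_given_y`` and ``y_given_x`` are the crosstalk (spillover) terms.
    """

    x_given_x: float
    x_given_y: float
    y_given_x: float
    y_given_y: float

    def __post_init__(self) -> None:
        for name in ("x_given_x", "x_given_y", "y_given_x", "y_given_y"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_given_x, self.x_given_y, self.y_given_x, self.y_given_y)


def _effective_inputs(params: NetworkParameters,
                      condition: InputCondition | None) -> tuple[float, float]:
    if condition is InputCondition.X_ON:
        return params.x0, 0.0
    if condition is InputCondition.Y_ON:
        return 0.0, params.y0
    return params.x0, params.y0


def _cs_gate(params: NetworkParameters, condition: InputCondition | None,
             x0: float, y0: float) -> float:
    # combinatorial gate: third-receptor input present under X, basal under Y
    if condition is InputCondition.X_ON:
        return 1.0
    if condition is InputCondition.Y_ON:
        return float(params.k_leak)  # type: ignore[arg-type]
    if x0 > 0 and y0 > 0:
        raise ParameterError("cs gate is undefined under simultaneous X and Y input")
    return float(params.k_leak) if y0 > 0 else 1.0


def rhs(params: NetworkParameters, state: Sequence[float],
        condition: InputCondition | None = None) -> np.ndarray:
    """Time-derivatives of the mechanism's ODE system at ``state``.

    State layout: ``(x1, x2, y2)`` for basic/cpi/cs; ``(x1n, x1c, x2, y2)``
    for sc.  If ``condition`` is given, the non-cognate input is clamped to
    zero; otherwise the parameter set's own (x0, y0) are used as-is.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (params.state_dim,):
        raise ValueError(
            f"state dimension {state.shape} does not match mechanism "
            f"{params.mechanism!r} (expected ({params.state_dim},))")
    x0, y0 = _effective_inputs(params, condition)
    p = params
    if p.mechanism == "sc":
        x1n, x1c, x2, y2 = state
        dx1n = p.a1 * x0 - p.D_out * x1n + p.D_in * x1c - p.d1x * x1n
        dx1c = p.b1 * y0 - p.D_in * x1c + p.D_out * x1n - p.d1y * x1c
        dx2 = p.a2 * evaluate_activation(p.fX, x1n) - p.d2x * x2
        dy2 = p.b2 * evaluate_activation(p.fY, x1c) - p.d2y * y2
        return np.array([dx1n, dx1c, dx2, dy2])
    x1, x2, y2 = state
    dx1 = p.a1 * x0 + p.b1 * y0 - p.d1x * x1
    prod_x2 = p.a2 * evaluate_activation(p.fX, x1)
    if p.mechanism == "cs":
        prod_x2 *= _cs_gate(p, condition, x0, y0)
    dx2 = prod_x2 - p.d2x * x2
    prod_y2 = p.b2 * evaluate_activation(p.fY, x1)
    if p.mechanism == "cpi":
        prod_y2 /= 1.0 + x2 / p.eps_g
    dy2 = prod_y2 - p.d2y * y2
    return np.array([dx1, dx2, dy2])


def _sc_pools(params: NetworkParameters, x0: float, y0: float) -> tuple[float, float]:
    """Solve the linear 2x2 system for the (anchored, cytosolic) pools."""
    p = params
    a11 = p.D_out + p.d1x
    a22 = p.D_in + p.d1y
    det = a11 * a22 - p.D_in * p.D_out
    bx = p.a1 * x0
    by = p.b1 * y0
    x1n = (a22 * bx + p.D_in * by) / det
    x1c = (p.D_out * bx + a11 * by) / det
    return x1n, x1c


def solve_steady_state_analytic(params: NetworkParameters,
                                condition: InputCondition) -> SteadyState:
    """Closed-form steady state under one exclusive input condition.

    The returned state zeroes the right-hand side exactly (up to floating
    point): the shared component relaxes to its linear fixed point and the
    outputs follow through the activation functions.
    """
    x0, y0 = _effective_inputs(params, condition)
    p = params
    if p.mechanism == "sc":
        x1n, x1c = _sc_pools(p, x0, y0)
        x2 = p.alpha * evaluate_activation(p.fX, x1n)
        y2 = p.beta * evaluate_activation(p.fY, x1c)
        return SteadyState(x2=x2, y2=y2, condition=condition, x1n=x1n, x1c=x1c)
    x1 = (p.a1 * x0 + p.b1 * y0) / p.d1x
    gate = _cs_gate(p, condition, x0, y0) if p.mechanism == "cs" else 1.0
    x2 = p.alpha * gate * evaluate_activation(p.fX, x1)
    y2 = p.beta * evaluate_activation(p.fY, x1)
    if p.mechanism == "cpi":
        y2 /= 1.0 + x2 / p.eps_g
    return SteadyState(x2=x2, y2=y2, condition=condition, x1=x1)


def solve_steady_state_numeric(params: NetworkParameters,
                               condition: InputCondition,
                               t_max: float = 1e6,
                               tol: float = 1e-10) -> SteadyState:
    """Steady state by stiff ODE integration from the all-zero state.

    Integrates in chunks until ||rhs||_inf < tol * (1 + ||state||_inf),
    raising :class:`ConvergenceError` if that is not reached by ``t_max``.
    """
    if t_max <= 0 or tol <= 0:
        raise ValueError("t_max and tol must be > 0")
    p = params
    fun = lambda t, s: rhs(p, s, condition)  # noqa: E731
    state = np.zeros(p.state_dim)
    rates = [p.d1x, p.d1y, p.d2x, p.d2y]
    if p.mechanism == "sc":
        rates += [r for r in (p.D_in, p.D_out) if r and r > 0]
    # slowest relaxation sets the horizon per chunk
    chunk = 50.0 / min(rates)
    t = 0.0
    while t < t_max:
        t_end = min(t + chunk, t_max)
        sol = solve_ivp(fun, (t, t_end), state, method="LSODA",
                        rtol=1e-12, atol=1e-14)
        if not sol.success:
            raise ConvergenceError(f"integration failed: {sol.message}")
        state = sol.y[:, -1]
        t = t_end
        resid = np.max(np.abs(fun(t, state)))
        if resid < tol * (1.0 + np.max(np.abs(state))):
            break
        chunk *= 2.0
    else:
        raise ConvergenceError(
            f"no steady state within t_max={t_max} (residual {resid:.3g})")
    if t >= t_max:
        resid = np.max(np.abs(fun(t, state)))
        if resid >= tol * (1.0 + np.max(np.abs(state))):
            raise ConvergenceError(
                f"no steady state within t_max={t_max} (residual {resid:.3g})")
    state = np.maximum(state, 0.0)
    if p.mechanism == "sc":
        return SteadyState(x2=state[2], y2=state[3], condition=condition,
                           x1n=state[0], x1c=state[1])
    return SteadyState(x2=state[1], y2=state[2], condition=condition, x1=state[0])


def output_quartet(params: NetworkParameters,
                   x_input_level: float | None = None,
                   y_input_level: float | None = None,
                   method: str = "analytic") -> OutputQuartet:
    """Steady-state outputs under X input and under Y input.

    Returns (X|X, X|Y, Y|X, Y|Y): the X output under its own and the other
    pathway's input, and likewise for Y.  Input levels default to the
    parameter set's ``x0``/``y0`` and must be positive.
    """
    p = params
    if x_input_level is not None or y_input_level is not None:
        p = replace(p, x0=float(x_input_level if x_input_level is not None else p.x0),
                    y0=float(y_input_level if y_input_level is not None else p.y0))
    if p.x0 <= 0 or p.y0 <= 0:
        raise ParameterError("output_quartet requires positive input levels for both pathways")
    solve = (solve_steady_state_analytic if method == "analytic"
             else solve_steady_state_numeric)
    on_x = solve(p, InputCondition.X_ON)
    on_y = solve(p, InputCondition.Y_ON)
    return OutputQuartet(x_given_x=on_x.x2, x_given_y=on_y.x2,
                         y_given_x=on_x.y2, y_given_y=on_y.y2)


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

_ACTIVATION_KEYS = {"activation", "n", "m", "eps_X", "eps_Y"}


def network_from_dict(doc: dict) -> NetworkParameters:
    """Build a parameter set from a flat config mapping.

    Field names mirror the model symbols: a1, b1, a2, b2, d1 (or d1x/d1y),
    d2x, d2y, n, m, eps_X, eps_Y, eps_g, k_leak, D_in, D_out, x0, y0,
    mechanism, activation (``linear`` or ``hill``; inferred as ``hill`` when
    n/m/eps keys are present).
    """
    doc = dict(doc)
    mech = doc.pop("mechanism", None)
    if mech not in MECHANISMS:
        raise ParameterError(f"config field 'mechanism' must be one of {MECHANISMS}, got {mech!r}")
    act = doc.pop("activation", None)
    if act is None:
        act = "hill" if any(k in doc for k in ("n", "m", "eps_X", "eps_Y")) else "linear"
    if act not in ("linear", "hill"):
        raise ParameterError(f"config field 'activation' must be linear or hill, got {act!r}")
    n = float(doc.pop("n", 1.0))
    m = float(doc.pop("m", 1.0))
    eps_x = float(doc.pop("eps_X", 1.0))
    eps_y = float(doc.pop("eps_Y", 1.0))
    if act == "linear":
        fX = fY = linear()
    else:
        fX, fY = hill(n, eps_x), hill(m, eps_y)
    if "d1" in doc:
        d1 = float(doc.pop("d1"))
        doc.setdefault("d1x", d1)
        doc.setdefault("d1y", d1)
    known = {"a1", "b1", "a2", "b2", "d1x", "d1y", "d2x", "d2y",
             "x0", "y0", "eps_g", "k_leak", "D_in", "D_out"}
    unknown = set(doc) - known
    if unknown:
        raise ParameterError(f"unknown config field(s): {sorted(unknown)}")
    defaults = dict(d1x=1.0, d1y=1.0, d2x=1.0, d2y=1.0, x0=1.0, y0=1.0)
    kwargs = {k: (float(doc[k]) if doc[k] is not None else None)
              for k in known if k in doc}
    for k, v in defaults.items():
        kwargs.setdefault(k, v)
    missing = {"a1", "b1", "a2", "b2"} - set(kwargs)
    if missing:
        raise ParameterError(f"missing required config field(s): {sorted(missing)}")
    try:
        return NetworkParameters(mechanism=mech, fX=fX, fY=fY, **kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ParameterError(str(exc)) from exc


def network_to_dict(params: NetworkParameters) -> dict:
    """Flat config mapping that round-trips through :func:`network_from_dict`."""
    doc: dict = {"mechanism": params.mechanism}
    for k in ("a1", "b1", "a2", "b2", "d1x", "d1y", "d2x", "d2y", "x0", "y0"):
        doc[k] = getattr(params, k)
    if params.fX.kind == "hill" or params.fY.kind == "hill":
        doc["activation"] = "hill"
        doc["n"] = params.fX.exponent
        doc["m"] = params.fY.exponent
        doc["eps_X"] = params.fX.threshold
        doc["eps_Y"] = params.fY.threshold
    else:
        doc["activation"] = "linear"
    for k in ("eps_g", "k_leak", "D_in", "D_out"):
        v = getattr(params, k)
        if v is not None:
            doc[k] = v
    return doc


def load_network(path) -> NetworkParameters:
    """Read one network parameter set from a YAML config file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParameterError(f"config {path} does not contain a mapping")
    return network_from_dict(doc)


def save_network(params: NetworkParameters, path) -> None:
    """Write a network parameter set as a YAML config file."""
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(params), fh, sort_keys=False)
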