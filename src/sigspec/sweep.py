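"""Randomized parameter ensembles and constrained MFMS maximization.

The sweep engine emulates a Monte-Carlo survey of network performance: rate
ratios are drawn over broad per-mechanism ranges (decay rates fixed at 1, so
a1 and b1 are directly the ratios a1/d1 and b1/d1; a2 and b2 are the
connection strengths alpha and beta), the Hill threshold of the Y branch is
drawn log-uniformly over three decades with eps_X fixed at 1, the
cross-regulatory term (CRT) is pinned (default 10) and the indicator set is
computed per trial at each point of a Hill-exponent grid.  The headline
statistic is a high percentile (default 90th) of the MFMS distribution as a
function of the exponents.

:func:`maximize_mfms` runs seeded differential evolution over the free
parameters at pinned CRT to probe how closely the closed-form MFMS ceilings
are approached (bound sharpness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from . import bounds as bounds_mod
from .metrics import UndefinedIndicatorError, specificity_indicators
from .models import NetworkParameters, hill, linear, output_quartet

__all__ = [
    "DEFAULT_RANGES",
    "MaximizeResult",
    "SweepConfig",
    "SweepResult",
    "max_mfms_random_sweep",
    "maximize_mfms",
    "nearest_rank_percentile",
    "run_sweep",
    "sample_parameters",
]

# Per-mechanism sampling ranges for the rate ratios (a1/d1, b1/d1, alpha,
# beta) and the Y-branch Hill threshold.  The X-branch threshold is fixed
# at 1, setting the concentration scale.
DEFAULT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "cpi": {"a1": (1.0, 5.0), "b1": (0.1, 1.0), "a2": (0.1, 5.0),
            "b2": (0.1, 5.0), "eps_Y": (0.01, 10.0)},
    "cs": {"a1": (0.1, 1.0), "b1": (1.0, 5.0), "a2": (0.1, 5.0),
           "b2": (0.1, 5.0), "eps_Y": (0.01, 10.0)},
    "sc": {"a1": (1.0, 5.0), "b1": (1.0, 5.0), "a2": (0.1, 5.0),
           "b2": (0.1, 5.0), "eps_Y": (0.01, 10.0)},
}

_CRT_SAMPLING_RANGE = (0.01, 100.0)


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of one randomized ensemble.

    exponent_grid
        Sequence of (n, m) Hill-exponent pairs at which every trial is
        evaluated.
    crt
        Pinned cross-regulatory strength (None samples CRT log-uniformly
        over [0.01, 100] per trial).
    ranges
        Per-parameter (low, high) sampling bounds; defaults to the
        mechanism's entry in :data:`DEFAULT_RANGES`.
    activation
        ``"hill"`` (default) or ``"linear"``; linear ignores the exponent
        grid beyond its length.
    """

    mechanism: str
    exponent_grid: tuple[tuple[float, float], ...] = ((1.0, 1.0),)
    trials: int = 10_000
    seed: int = 0
    percentile: float = 0.9
    crt: float | None = 10.0
    ranges: dict | None = None
    eps_x: float = 1.0
    activation: str = "hill"
    ratio_sampling: str = "uniform"
    eps_y_sampling: str = "log"

    def __post_init__(self) -> None:
        if self.mechanism not in DEFAULT_RANGES:
            raise ValueError(f"sweep mechanism must be one of {tuple(DEFAULT_RANGES)}")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must be in (0, 1)")
        if self.activation not in ("hill", "linear"):
            raise ValueError("activation must be hill or linear")
        if self.ranges is None:
            object.__setattr__(self, "ranges", dict(DEFAULT_RANGES[self.mechanism]))
        grid = tuple((float(n), float(m)) for n, m in self.exponent_grid)
        object.__setattr__(self, "exponent_grid", grid)

    # common grids ----------------------------------------------------------

    @classmethod
    def vary_n(cls, mechanism: str, n_values, m: float = 1.0, **kw) -> "SweepConfig":
        return cls(mechanism, tuple((float(n), float(m)) for n in n_values), **kw)

    @classmethod
    def vary_m(cls, mechanism: str, m_values, n: float = 1.0, **kw) -> "SweepConfig":
        return cls(mechanism, tuple((float(n), float(m)) for m in m_values), **kw)

    @classmethod
    def vary_joint(cls, mechanism: str, values, **kw) -> "SweepConfig":
        return cls(mechanism, tuple((float(v), float(v)) for v in values), **kw)


def _mechanism_kwargs(mechanism: str, crt: float, alpha: float) -> dict:
    if mechanism == "cpi":
        return {"eps_g": alpha / crt}
    if mechanism == "cs":
        if crt < 1:
            raise ValueError("cs requires CRT >= 1 (k_leak <= 1)")
        return {"k_leak": 1.0 / crt}
    return {"D_in": 1.0 / crt, "D_out": 1.0 / crt}


def sample_parameters(config: SweepConfig, draw_index: int) -> NetworkParameters:
    """Deterministic parameter draw for one trial.

    The random stream is keyed on (seed, draw_index), so a draw is fully
    reproducible in isolation.  Hill exponents are placeholders (1, 1); the
    sweep replaces them per grid point.
    """
    rng = np.random.default_rng([config.seed, int(draw_index)])
    r = config.ranges

    def ratio(name: str) -> float:
        lo, hi = r[name]
        if config.ratio_sampling == "log":
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return float(rng.uniform(lo, hi))

    a1, b1, a2, b2 = (ratio(k) for k in ("a1", "b1", "a2", "b2"))
    lo, hi = r["eps_Y"]
    if config.eps_y_sampling == "log":
        eps_y = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    else:
        eps_y = float(rng.uniform(lo, hi))
    crt = config.crt
    if crt is None:
        crt = float(np.exp(rng.uniform(*np.log(_CRT_SAMPLING_RANGE))))
    if config.activation == "linear":
        fX, fY = linear(), linear()
    else:
        fX, fY = hill(1.0, config.eps_x), hill(1.0, eps_y)
    mech_kw = _mechanism_kwargs(config.mechanism, crt, a2 / 1.0)
    common = dict(a1=a1, b1=b1, a2=a2, b2=b2, d2x=1.0, d2y=1.0,
                  fX=fX, fY=fY, x0=1.0, y0=1.0)
    if config.mechanism == "sc":
        return NetworkParameters.sc(d1x=1.0, d1y=1.0, **common, **mech_kw)
    ctor = getattr(NetworkParameters, config.mechanism)
    return ctor(d1=1.0, **common, **mech_kw)


def nearest_rank_percentile(values, q: float) -> float:
    """Nearest-rank percentile; +inf values sort above all finite ones."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("no values to take a percentile of")
    k = max(1, math.ceil(q * arr.size))
    return float(arr[k - 1])


@dataclass
class SweepResult:
    """Per-trial indicator records plus the percentile-vs-exponent curve."""

    config: SweepConfig
    records: pd.DataFrame
    curve: pd.DataFrame
    n_dropped: int = 0

    def write_csv(self, records_path, curve_path=None) -> None:
        self.records.to_csv(records_path, index=False)
        if curve_path is not None:
            self.curve.to_csv(curve_path, index=False)

    def summary(self) -> dict:
        return {
            "mechanism": self.config.mechanism,
            "trials": self.config.trials,
            "seed": self.config.seed,
            "percentile": self.config.percentile,
            "crt": self.config.crt,
            "n_dropped": self.n_dropped,
            "curve": self.curve.to_dict(orient="records"),
        }


def run_sweep(config: SweepConfig) -> SweepResult:
    """Evaluate the indicator set for every trial at every exponent pair.

    Draws are reused (paired) across the exponent grid so percentile curves
    vary only through the exponents.  Trials whose indicators are undefined
    (0/0 crosstalk ratios) are dropped and counted in ``n_dropped``.
    """
    rows = []
    dropped = 0
    for draw in range(config.trials):
        base = sample_parameters(config, draw)
        for n, m in config.exponent_grid:
            params = base if config.activation == "linear" else base.with_exponents(n, m)
            try:
                ind = specificity_indicators(output_quartet(params))
            except UndefinedIndicatorError:
                dropped += 1
                continue
            rows.append({
                "draw": draw, "n": n, "m": m,
                "a1": params.a1, "b1": params.b1,
                "alpha": params.alpha, "beta": params.beta,
                "eps_Y": params.fY.threshold if params.fY.kind == "hill" else np.nan,
                "S_X": ind.s_x, "S_Y": ind.s_y, "F_X": ind.f_x,
                "F_Y": ind.f_y, "MFMS": ind.mfms,
            })
    records = pd.DataFrame(rows)
    curve_rows = []
    for n, m in config.exponent_grid:
        sel = records[(records["n"] == n) & (records["m"] == m)]["MFMS"]
        curve_rows.append({"n": n, "m": m,
                           "percentile_mfms": nearest_rank_percentile(sel, config.percentile)})
    return SweepResult(config=config, records=records,
                       curve=pd.DataFrame(curve_rows), n_dropped=dropped)


# ---------------------------------------------------------------------------
# constrained maximization at pinned CRT
# ---------------------------------------------------------------------------


@dataclass
class MaximizeResult:
    """Best MFMS found at pinned CRT, with the realizing parameter set."""

    mfms: float
    params: NetworkParameters
    bound: float
    below_bound: bool
    n_evaluations: int


def _build_network(mechanism: str, crt: float, u: float, v: float,
                   alpha: float, beta: float, fX, fY) -> NetworkParameters:
    common = dict(a1=u, b1=v, a2=alpha, b2=beta, d2x=1.0, d2y=1.0,
                  fX=fX, fY=fY, x0=1.0, y0=1.0)
    kw = _mechanism_kwargs(mechanism, crt, alpha)
    if mechanism == "sc":
        return NetworkParameters.sc(d1x=1.0, d1y=1.0, **common, **kw)
    return getattr(NetworkParameters, mechanism)(d1=1.0, **common, **kw)


def _mfms_of(params: NetworkParameters) -> float:
    try:
        return specificity_indicators(output_quartet(params)).mfms
    except UndefinedIndicatorError:
        return 0.0


def maximize_mfms(mechanism: str, activation: str, crt: float,
                  budget: int = 30_000, seed: int = 0,
                  n: float | None = None, m: float | None = None) -> MaximizeResult:
    """Search for the largest MFMS the mechanism can reach at fixed CRT.

    Seeded differential evolution over log-scaled free parameters (inputs
    u = a1*x0 and v = b1*y0, connection strengths alpha and beta, and for
    Hill activation the thresholds and — unless pinned — the exponents in
    [1, 10]), followed by the optimizer's local polish.  The result never
    exceeds the corresponding closed-form ceiling; ``below_bound`` records
    whether it stayed strictly below.
    """
    if activation not in ("linear", "ultrasensitive"):
        raise ValueError("activation must be linear or ultrasensitive")
    lo, hi = -2.0, 2.0  # decades for log10-scaled positive parameters
    bounds_list = [(lo, hi)] * 4
    vary_exponents = activation == "ultrasensitive" and (n is None or m is None)
    if activation == "ultrasensitive":
        bounds_list += [(lo, hi), (lo, hi)]
        if n is None:
            bounds_list.append((1.0, 10.0))
        if m is None:
            bounds_list.append((1.0, 10.0))

    def decode(x) -> NetworkParameters:
        u, v, alpha, beta = (10.0 ** xi for xi in x[:4])
        if activation == "linear":
            fX, fY = linear(), linear()
        else:
            eps_x, eps_y = 10.0 ** x[4], 10.0 ** x[5]
            idx = 6
            nn = n if n is not None else float(np.clip(x[idx], 1.0, 10.0))
            idx += n is None
            mm = m if m is not None else float(np.clip(x[idx], 1.0, 10.0))
            fX, fY = hill(nn, eps_x), hill(mm, eps_y)
        return _build_network(mechanism, crt, u, v, alpha, beta, fX, fY)

    evals = 0

    def objective(x) -> float:
        nonlocal evals
        evals += 1
        return -_mfms_of(decode(x))

    ndim = len(bounds_list)
    popsize = 16
    maxiter = max(20, budget // (popsize * ndim))
    res = optimize.differential_evolution(
        objective, bounds_list, seed=seed, maxiter=maxiter, popsize=popsize,
        tol=0.0, mutation=(0.3, 1.2), recombination=0.9, polish=True,
        init="sobol")
    best = -float(res.fun)
    best_params = decode(res.x)
    if activation == "ultrasensitive" and mechanism == "sc":
        n_bound = n if n is not None else best_params.fX.exponent
        bound = bounds_mod.mfms_bound(
            bounds_mod.BoundSpec("sc", "ultrasensitive", crt, n=n_bound))
    else:
        bound = bounds_mod.mfms_bound(bounds_mod.BoundSpec(mechanism, activation, crt))
    return MaximizeResult(mfms=best, params=best_params, bound=bound,
                          below_bound=best <= bound, n_evaluations=evals)


def max_mfms_random_sweep(mechanism: str, activation: str = "linear",
                          trials: int = 10_000, seed: int = 0,
                          crt: float | None = None,
                          refine: bool = True,
                          refine_budget: int = 4_000) -> tuple[float, NetworkParameters]:
    """Maximum MFMS over a randomized sweep, with optional local refinement.

    Trials draw rate ratios from the mechanism's standard ranges and, when
    ``crt`` is None, the CRT log-uniformly over [0.01, 100] (for cpi that is
    the IC50 eps_g spanning several decades around alpha).  The best draws
    are then polished by Nelder-Mead within the same box constraints.
    """
    config = SweepConfig(mechanism, ((1.0, 1.0),), trials=trials, seed=seed,
                         crt=crt, activation=activation)
    best_val, best_draw = -np.inf, None
    vals = []
    for draw in range(trials):
        params = sample_parameters(config, draw)
        val = _mfms_of(params)
        vals.append((val, draw))
        if val > best_val:
            best_val, best_draw = val, draw
    best_params = sample_parameters(config, best_draw)
    if not refine:
        return best_val, best_params
    # Nelder-Mead polish of the top draws inside the sampling box
    r = config.ranges
    names = ["a1", "b1", "a2", "b2"]
    box = [r[k] for k in names] + [np.log10(_CRT_SAMPLING_RANGE)
                                   if crt is None else None]

    def rebuild(x, base: NetworkParameters) -> NetworkParameters:
        kw = dict(a1=x[0], b1=x[1], a2=x[2], b2=x[3], d2x=1.0, d2y=1.0,
                  fX=base.fX, fY=base.fY, x0=1.0, y0=1.0)
        crt_val = 10.0 ** x[4] if crt is None else crt
        mech_kw = _mechanism_kwargs(mechanism, crt_val, x[2])
        if mechanism == "sc":
            return NetworkParameters.sc(d1x=1.0, d1y=1.0, **kw, **mech_kw)
        return getattr(NetworkParameters, mechanism)(d1=1.0, **kw, **mech_kw)

    vals.sort(reverse=True)
    for _, draw in vals[:5]:
        base = sample_parameters(config, draw)
        from .metrics import cross_regulatory_term
        x0 = [base.a1, base.b1, base.a2, base.b2]
        nm_bounds = box[:4]
        if crt is None:
            x0.append(np.log10(cross_regulatory_term(base)))
            nm_bounds = box
        else:
            nm_bounds = box[:4]
        res = optimize.minimize(
            lambda x: -_mfms_of(rebuild(x, base)), x0, method="Nelder-Mead",
            bounds=nm_bounds,
            options={"maxfev": refine_budget // 5, "xatol": 1e-10, "fatol": 1e-12})
        if -res.fun > best_val:
            best_val = -float(res.fun)
            best_params = rebuild(res.x, base)
    return best_val, best_params
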