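"""Specificity and fidelity indicators for two-pathway networks.

Output specificity S measures how much a pathway's input activates its own
output relative to the other pathway's output; input fidelity F measures how
much a pathway's output responds to its own input relative to the other
pathway's input:

    S_X = (X|X)/(Y|X)   S_Y = (Y|Y)/(X|Y)
    F_X = (X|X)/(X|Y)   F_Y = (Y|Y)/(Y|X)

The composites MS = min(S_X, S_Y), MF = min(F_X, F_Y) and
MFMS = min(MS, MF) summarize the network: MFMS > 1 means every indicator
exceeds 1 simultaneously, i.e. the network communicates faithfully through
both pathways.

A positive output over a zero crosstalk term yields +inf (a pathway with no
spillover has perfect specificity); 0/0 signals a degenerate network and
raises :class:`UndefinedIndicatorError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .models import NetworkParameters, OutputQuartet

__all__ = [
    "CrossRegulationError",
    "OutputQuartet",
    "SpecificityIndicators",
    "UndefinedIndicatorError",
    "cross_regulatory_term",
    "normalized_indicators",
    "normalized_quartet",
    "specificity_indicators",
]


class UndefinedIndicatorError(ValueError):
    """A 0/0 indicator ratio: both cognate and crosstalk outputs vanish."""


class CrossRegulationError(ValueError):
    """The mechanism has no cross-regulatory term, or its reduction fails."""


@dataclass(frozen=True)
class SpecificityIndicators:
    """The four indicators plus the MS/MF/MFMS composites.

    ``normalized`` marks indicators computed on diagonal-rescaled outputs,
    for which s_x == f_y and s_y == f_x hold identically.
    """

    s_x: float
    s_y: float
    f_x: float
    f_y: float
    ms: float
    mf: float
    mfms: float
    normalized: bool = False

    def to_dict(self) -> dict:
        return {"S_X": self.s_x, "S_Y": self.s_y, "F_X": self.f_x,
                "F_Y": self.f_y, "MS": self.ms, "MF": self.mf,
                "MFMS": self.mfms, "normalized": self.normalized}


def _ratio(num: float, den: float) -> float:
    if den > 0:
        return num / den
    if num > 0:
        return math.inf
    raise UndefinedIndicatorError(
        "0/0 indicator: both outputs vanish (degenerate network)")


def specificity_indicators(q: OutputQuartet) -> SpecificityIndicators:
    """Compute S_X, S_Y, F_X, F_Y and their composites from a quartet."""
    s_x = _ratio(q.x_given_x, q.y_given_x)
    s_y = _ratio(q.y_given_y, q.x_given_y)
    f_x = _ratio(q.x_given_x, q.x_given_y)
    f_y = _ratio(q.y_given_y, q.y_given_x)
    ms = min(s_x, s_y)
    mf = min(f_x, f_y)
    return SpecificityIndicators(s_x=s_x, s_y=s_y, f_x=f_x, f_y=f_y,
                                 ms=ms, mf=mf, mfms=min(ms, mf))


def normalized_quartet(q: OutputQuartet) -> OutputQuartet:
    """Rescale each output column by its cognate diagonal entry.

    After normalization X|X = Y|Y = 1 and the crosstalk terms are expressed
    as fractions of the cognate steady-state response.
    """
    if q.x_given_x <= 0 or q.y_given_y <= 0:
        raise UndefinedIndicatorError(
            "normalization requires positive cognate outputs X|X and Y|Y")
    return OutputQuartet(x_given_x=1.0,
                         x_given_y=q.x_given_y / q.x_given_x,
                         y_given_x=q.y_given_x / q.y_given_y,
                         y_given_y=1.0)


def normalized_indicators(q: OutputQuartet) -> SpecificityIndicators:
    """Indicators on the diagonal-normalized quartet.

    With outputs expressed relative to their own cognate response,
    specificity in one pathway coincides with fidelity in the other:
    s_x == f_y = (Y|Y)/(Y|X) and s_y == f_x = (X|X)/(X|Y), so mutual
    specificity and mutual fidelity become the same objective.
    """
    ind = specificity_indicators(normalized_quartet(q))
    return SpecificityIndicators(s_x=ind.s_x, s_y=ind.s_y, f_x=ind.f_x,
                                 f_y=ind.f_y, ms=ind.ms, mf=ind.mf,
                                 mfms=ind.mfms, normalized=True)


def cross_regulatory_term(params: NetworkParameters) -> float:
    """Dimensionless strength of the insulating mechanism (CRT).

    cpi: alpha/eps_g; cs: 1/k_leak (+inf when the leak is fully closed);
    sc: d1/D with the symmetric reduction D_in = D_out = D and d1x = d1y.
    The basic architecture has no cross regulation and raises.
    """
    p = params
    if p.mechanism == "basic":
        raise CrossRegulationError("the basic architecture has no cross-regulatory term")
    if p.mechanism == "cpi":
        return p.alpha / p.eps_g  # type: ignore[operator]
    if p.mechanism == "cs":
        return math.inf if p.k_leak == 0 else 1.0 / p.k_leak  # type: ignore[operator]
    if p.D_in != p.D_out:
        raise CrossRegulationError("sc CRT requires symmetric exchange D_in == D_out")
    if p.d1x != p.d1y:
        raise CrossRegulationError("sc CRT requires d1x == d1y")
    return math.inf if p.D_in == 0 else p.d1x / p.D_in  # type: ignore[operator]
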