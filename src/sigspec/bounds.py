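"""Closed-form MFMS ceilings per insulating mechanism at fixed cross regulation.

At a fixed cross-regulatory term (CRT), each mechanism/activation pair has a
maximal attainable MFMS:

==========  ==========  =======================================
mechanism   activation  max MFMS
==========  ==========  =======================================
cpi         linear      1
cpi         hill        1 + CRT            (strict, approached)
cs          linear      sqrt(CRT)
cs          hill        CRT                (strict, approached)
sc          linear      1 + CRT            (attained)
sc          hill, n=m   (1 + CRT)^n ceiling; the symmetric
                        network attains an exact closed form
==========  ==========  =======================================

The linear-cs value deserves a note: the four linear-CS indicators are
min{alpha/beta, (beta/alpha)*CRT, (x1X/x1Y)*CRT, x1Y/x1X}, whose maximum over
the two free ratios is the geometric mean sqrt(CRT) of each pair, reached at
alpha/beta = sqrt(CRT) and x1X/x1Y = 1/sqrt(CRT).  Tests confirm this against
a brute-force optimization of the full network.

For scaffolding/compartmentalization with symmetric parameters
(a1 = b1 = a, alpha = beta, n = m, eps_X = eps_Y = 1, d1 = 1, D = 1/CRT) the
network's MFMS is exactly

    [a^n (1+CRT)^n + (1+CRT)^n (2+CRT)^n] / [a^n (1+CRT)^n + (2+CRT)^n]

which grows like (1+CRT)^n: super-linear in CRT whenever n > 1, in contrast
to the linear growth available to cpi and cs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import NetworkParameters, hill

__all__ = [
    "BoundSpec",
    "bound_curve",
    "hill_fold_change",
    "mfms_bound",
    "sc_symmetric_mfms",
    "sc_symmetric_network",
]


def hill_fold_change(n: float, lo: float = 0.1, hi: float = 0.9) -> float:
    """Input fold-change moving a Hill output from fraction ``lo`` to ``hi``.

    For f(u) = u^n/(u^n + eps^n), the input giving fractional output p is
    eps * (p/(1-p))^(1/n), so the ratio of inputs at ``hi`` and ``lo`` is
    [hi (1-lo) / (lo (1-hi))]^(1/n) — 81^(1/n) for the canonical 10%→90%
    window: 81 for a hyperbolic response, 9 and 3 for n = 2 and 4.
    """
    if not (0 < lo < hi < 1):
        raise ValueError(f"need 0 < lo < hi < 1, got lo={lo}, hi={hi}")
    if n < 1:
        raise ValueError(f"Hill exponent must be >= 1, got {n}")
    return (hi * (1 - lo) / (lo * (1 - hi))) ** (1.0 / n)


@dataclass(frozen=True)
class BoundSpec:
    """Which bound to evaluate: mechanism, activation class, CRT, and the
    symmetric-sc extras (Hill exponent ``n``, input strength ``a``)."""

    mechanism: str
    activation: str
    crt: float
    n: float | None = None
    a: float | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("cpi", "cs", "sc"):
            raise ValueError(f"no MFMS bound for mechanism {self.mechanism!r}")
        if self.activation not in ("linear", "ultrasensitive"):
            raise ValueError(
                f"activation must be linear or ultrasensitive, got {self.activation!r}")
        if self.crt < 0:
            raise ValueError("CRT must be >= 0")
        if self.mechanism == "sc" and self.activation == "ultrasensitive" and self.n is None:
            raise ValueError("sc/ultrasensitive bound requires the Hill exponent n")


def mfms_bound(spec: BoundSpec) -> float:
    """Maximal MFMS at the spec's fixed CRT.

    For sc/ultrasensitive: the exact symmetric-network value when the input
    strength ``a`` is given, else the general n = m ceiling (1 + CRT)^n,
    which is also the a → 0 limit of the exact expression.
    """
    crt = spec.crt
    if spec.activation == "linear":
        if spec.mechanism == "cpi":
            return 1.0
        if spec.mechanism == "cs":
            return math.sqrt(crt)
        return 1.0 + crt
    if spec.mechanism == "cpi":
        return 1.0 + crt
    if spec.mechanism == "cs":
        return crt
    if spec.a is not None:
        return sc_symmetric_mfms(spec.a, crt, spec.n)  # type: ignore[arg-type]
    return (1.0 + crt) ** spec.n  # type: ignore[operator]


def sc_symmetric_mfms(a: float, crt: float, n: float) -> float:
    """Exact MFMS of the symmetric scaffolding/compartmentalization network.

    Under the symmetric conventions (a1 = b1 = a with unit inputs,
    alpha = beta, n = m, eps_X = eps_Y = 1, d1 = 1, D = 1/CRT) all four
    indicators coincide, and MFMS equals

        [a^n (1+CRT)^n + (1+CRT)^n (2+CRT)^n] / [a^n (1+CRT)^n + (2+CRT)^n]

    asymptotically ~ (1+CRT)^n for large CRT.  This is an equality for the
    symmetric network, not merely an upper bound.
    """
    if a <= 0 or crt < 0 or n < 1:
        raise ValueError("need a > 0, crt >= 0, n >= 1")
    an = a ** n
    p1 = (1.0 + crt) ** n
    p2 = (2.0 + crt) ** n
    return (an * p1 + p1 * p2) / (an * p1 + p2)


def sc_symmetric_network(a: float, crt: float, n: float) -> NetworkParameters:
    """The symmetric sc network realizing :func:`sc_symmetric_mfms`.

    Pinned scaling: d1x = d1y = 1, D_in = D_out = 1/CRT, a1 = b1 = a with
    x0 = y0 = 1, alpha = beta = 1, Hill thresholds 1, exponents n = m.
    Requires crt > 0 (finite exchange).
    """
    if crt <= 0:
        raise ValueError("the explicit network requires crt > 0")
    D = 1.0 / crt
    return NetworkParameters.sc(D_in=D, D_out=D, a1=a, b1=a, a2=1.0, b2=1.0,
                                d1x=1.0, d1y=1.0, d2x=1.0, d2y=1.0,
                                fX=hill(n, 1.0), fY=hill(n, 1.0),
                                x0=1.0, y0=1.0)


def bound_curve(mechanism: str, activation: str, crt_values,
                n: float | None = None, a: float | None = None) -> pd.DataFrame:
    """Tabulate the MFMS bound over a range of CRT values (for plotting)."""
    crt_values = np.asarray(crt_values, dtype=float)
    rows = [{"crt": c, "mechanism": mechanism, "activation": activation,
             "n": n, "bound": mfms_bound(BoundSpec(mechanism, activation, c, n=n, a=a))}
            for c in crt_values]
    return pd.DataFrame(rows)
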