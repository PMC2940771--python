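"""Shared fixtures: randomized valid network instances."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import sigspec as sg

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def _log_uniform(rng, lo, hi):
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def make_random_network(rng: np.random.Generator, mechanism: str,
                        activation: str = "hill",
                        max_exponent: float = 4.0) -> sg.NetworkParameters:
    """A random valid parameter set with rates spanning ~[0.1, 5].

    Exponents are kept moderate and thresholds within [0.1, 3] so that no
    output underflows, which keeps relative comparisons meaningful.
    """
    def r(lo=0.1, hi=5.0):
        return _log_uniform(rng, lo, hi)

    if activation == "hill":
        fX = sg.hill(float(rng.uniform(1.0, max_exponent)), r(0.1, 3.0))
        fY = sg.hill(float(rng.uniform(1.0, max_exponent)), r(0.1, 3.0))
    else:
        fX, fY = sg.linear(), sg.linear()
    kw = dict(a1=r(), b1=r(), a2=r(), b2=r(), d2x=r(), d2y=r(),
              fX=fX, fY=fY, x0=r(), y0=r())
    if mechanism == "basic":
        return sg.NetworkParameters.basic(d1=r(), **kw)
    if mechanism == "cpi":
        return sg.NetworkParameters.cpi(d1=r(), eps_g=r(0.05, 20.0), **kw)
    if mechanism == "cs":
        return sg.NetworkParameters.cs(d1=r(), k_leak=float(rng.uniform(0.01, 1.0)), **kw)
    return sg.NetworkParameters.sc(d1x=r(), d1y=r(), D_in=r(0.01, 10.0),
                                   D_out=r(0.01, 10.0), **kw)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240501)


@pytest.fixture
def random_network():
    return make_random_network
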