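"""Shared fixtures and independent oracles.

The polyprotic pH oracle below deliberately avoids the package's
Newton-Raphson machinery: it reduces a single-acid model to the scalar
proton-balance equation and solves it by bracketing/bisection (brentq), so
solver results can be checked against an independent route.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from eqspec.model import Component, EquilibriumModel, Species


def make_acid_model(lnbs, water_lnkw=math.log(1e-14)):
    """Single polyprotic acid HnA: species H_kA with cumulative ln beta."""
    species = [
        Species(f"H{k}A" if k > 1 else "HA", (1, k), lnb_fixed=lnb)
        for k, lnb in enumerate(lnbs, start=1)
    ]
    return EquilibriumModel(
        [Component("A"), Component("H", role="proton")],
        species,
        water=(0.0, 8.31 * water_lnkw),
    )


def make_vant_hoff_acid(pairs, water=(0.0, 8.31 * math.log(1e-14))):
    """Like :func:`make_acid_model` but with (dH, dS) thermodynamics."""
    species = [
        Species(f"H{k}A" if k > 1 else "HA", (1, k), dh=dh, ds=ds, free=True)
        for k, (dh, ds) in enumerate(pairs, start=1)
    ]
    return EquilibriumModel(
        [Component("A"), Component("H", role="proton")], species, water=water
    )


def bisection_ph(lnbs, a_tot, h_tot, lnkw=math.log(1e-14)):
    """Independent pH oracle for a single polyprotic acid.

    Solves the scalar proton balance
        h + a_tot * sum(k b_k h^k) / (1 + sum(b_k h^k)) - Kw/h - h_tot = 0
    by brentq on a wide bracket; monotone increasing in h.
    """
    betas = [math.exp(lnb) for lnb in lnbs]
    kw = math.exp(lnkw)

    def g(log_h):
        h = math.exp(log_h)
        powers = [b * h ** k for k, b in enumerate(betas, start=1)]
        denom = 1.0 + sum(powers)
        bound = a_tot * sum(k * p for k, p in enumerate(powers, start=1)) / denom
        return h + bound - kw / h - h_tot

    lo, hi = math.log(1e-16), math.log(100.0)
    root = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=300)
    return -root / math.log(10.0)


@pytest.fixture(scope="session")
def monoprotic():
    """HA model with beta = 1e5 (Ka = 1e-5), no water."""
    return EquilibriumModel(
        [Component("A"), Component("H", role="proton")],
        [Species("HA", (1, 1), lnb_fixed=math.log(1e5))],
        include_water=False,
    )


@pytest.fixture(scope="session")
def pure_water():
    """Proton-only model with Kw fixed at exactly 1e-14."""
    return EquilibriumModel(
        [Component("H", role="proton")], [], water=(0.0, 8.31 * math.log(1e-14))
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260905)
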