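"""Newton-Raphson speciation: free concentrations from mass balances.

Given total analytical concentrations of the components, the solver finds
free component concentrations such that, with every species concentration
computed by the mass-action law

    [species] = beta(T) * prod_k free_k ** coeff_k,

the coefficient-weighted species sums reproduce the totals.  The proton
balance includes -[OH-]; negative proton totals (excess base) are legal.

The iteration runs on the logarithms of the free concentrations, which makes
positivity structural and — because the mass-balance map is the gradient of
the convex potential  sum_i [species_i] - sum_k totals_k * ln free_k  — lets
a damped (step-halved) Newton method converge from poor starting points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import SolverError
from .model import EquilibriumModel

#: Relative convergence tolerance on the mass-balance residuals.
DEFAULT_RTOL = 1e-12

#: Absolute concentration floor used for tolerance scaling (mol/L).
SCALE_FLOOR = 1e-8

#: Concentration floor for initial guesses (mol/L).
GUESS_FLOOR = 1e-10

MAX_ITER = 200
MAX_HALVINGS = 40
_EXP_CLIP = 600.0


@dataclass
class SpeciationState:
    """Free and full species concentrations at one equilibrium point."""

    free: np.ndarray          # mol/L per component
    species_conc: np.ndarray  # mol/L per species
    totals_given: np.ndarray
    totals_calc: np.ndarray
    diff: np.ndarray          # totals_given - totals_calc
    converged: bool
    iterations: int
    T: float
    model: EquilibriumModel

    def free_of(self, name: str) -> float:
        return float(self.free[self.model.component_names.index(name)])

    def conc_of(self, name: str) -> float:
        return float(self.species_conc[self.model.species_index(name)])


def _totals_array(model: EquilibriumModel, totals) -> np.ndarray:
    if isinstance(totals, Mapping):
        unknown = set(totals) - set(model.component_names)
        if unknown:
            raise ValueError(f"unknown components in totals: {sorted(unknown)}")
        return np.array([float(totals.get(n, 0.0)) for n in model.component_names])
    arr = np.asarray(totals, dtype=float)
    if arr.shape != (model.n_components,):
        raise ValueError("totals length does not match component count")
    return arr.copy()


def species_concentrations(
    free, model: EquilibriumModel, T: float
) -> np.ndarray:
    """Species concentrations from free component concentrations (mass action).

    Components with free concentration exactly zero annihilate every species
    containing them with a positive coefficient; a zero free proton is
    rejected when hydroxide-type species (negative proton coefficient) exist.
    """
    free = _totals_array(model, free) if not isinstance(free, np.ndarray) else np.asarray(free, float)
    if free.shape != (model.n_components,):
        free = _totals_array(model, free)
    N = model.stoich_matrix
    if np.any(free < 0):
        neg = np.where(free < 0)[0]
        if np.any(N[:, neg] > 0):
            raise ValueError("negative free concentration for a component")
    lnb = model.lnb_vector(T)
    conc = np.empty(model.n_species)
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(free > 0, np.log(np.where(free > 0, free, 1.0)), -np.inf)
    for i in range(model.n_species):
        row = N[i]
        if np.any((row > 0) & (free == 0.0)):
            conc[i] = 0.0
            continue
        if np.any((row < 0) & (free == 0.0)):
            raise ValueError(
                f"species {model.species[i].name!r} needs a positive free "
                "concentration for its negative-coefficient component"
            )
        expo = lnb[i] + float(row @ np.where(np.isfinite(logf), logf, 0.0))
        conc[i] = np.exp(min(expo, _EXP_CLIP))
    return conc


def mass_balance(free, totals_given, model: EquilibriumModel, T: float) -> np.ndarray:
    """diff = totals_given - coefficient-weighted species sums at ``free``."""
    totals_given = _totals_array(model, totals_given)
    conc = species_concentrations(free, model, T)
    totals_calc = model.stoich_matrix.T @ conc
    return totals_given - totals_calc


def _initial_guess(totals: np.ndarray, proton: int | None) -> np.ndarray:
    guess = np.maximum(np.abs(totals), GUESS_FLOOR) * 1e-2
    if proton is not None and totals[proton] <= 0:
        guess[proton] = 1e-7
    return guess


def solve_free_concentrations(
    model: EquilibriumModel,
    totals_given,
    T: float,
    initial_guess=None,
    fixed_free: Mapping | None = None,
    rtol: float = DEFAULT_RTOL,
    max_iter: int = MAX_ITER,
) -> SpeciationState:
    """Solve the mass-balance system for free component concentrations.

    Parameters
    ----------
    totals_given:
        Total analytical concentrations, dict or array over components.
        Must be non-negative except for the proton (excess base).
    initial_guess:
        Optional starting free concentrations (typically the previous
        titration point, for warm starts).
    fixed_free:
        Components whose *free* concentration is clamped (their mass balance
        is dropped); used for pH-targeted speciation where [H+] is imposed.

    Raises
    ------
    SolverError
        On non-convergence; the exception carries the last state.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    totals = _totals_array(model, totals_given)
    if not np.all(np.isfinite(totals)):
        raise ValueError("totals must be finite")
    nc = model.n_components
    proton = model.proton_index
    for k in range(nc):
        if k != proton and totals[k] < 0:
            raise ValueError(
                f"negative total for component {model.component_names[k]!r}"
            )
    fixed_free = dict(fixed_free or {})
    fixed_idx = {}
    for name, val in fixed_free.items():
        i = model.component_names.index(name)
        if val <= 0:
            raise ValueError(f"fixed free concentration for {name!r} must be > 0")
        fixed_idx[i] = float(val)

    # partition components: fixed / structurally-zero / unknown
    zero = [
        k
        for k in range(nc)
        if k != proton and k not in fixed_idx and totals[k] == 0.0
    ]
    unknown = [k for k in range(nc) if k not in fixed_idx and k not in zero]

    N = model.stoich_matrix
    lnb = model.lnb_vector(T)
    # species alive given structurally-zero components
    alive = ~np.any(N[:, zero] > 0, axis=1) if zero else np.ones(model.n_species, bool)
    Na = N[alive]
    lnb_a = lnb[alive].copy()
    for i, val in fixed_idx.items():
        lnb_a = lnb_a + Na[:, i] * np.log(val)
    Nu = Na[:, unknown]
    t_u = totals[unknown]

    guess = np.asarray(initial_guess, float) if initial_guess is not None else None
    if guess is None:
        guess = _initial_guess(totals, proton)
    x = np.log(np.maximum(guess[unknown], 1e-30))

    scale = np.maximum(np.abs(t_u), SCALE_FLOOR)
    Nu_abs = np.abs(Nu)

    def evaluate(xv):
        expo = np.minimum(lnb_a + Nu @ xv, _EXP_CLIP)
        conc = np.exp(expo)
        tc = Nu.T @ conc
        pot = conc.sum() - float(t_u @ xv)
        # tolerance: relative to the totals plus a roundoff allowance for
        # cancellation between large species terms (e.g. [HA] vs [OH-] in a
        # near-neutral proton balance)
        gross = Nu_abs.T @ conc
        tol = rtol * scale + 1e-13 * gross
        res = np.max(np.abs(tc - t_u) / tol) if len(t_u) else 0.0
        return conc, tc, pot, res

    conc, tc, pot, res = evaluate(x)
    iterations = 0
    converged = res <= 1.0
    while not converged and iterations < max_iter:
        iterations += 1
        J = (Nu * conc[:, None]).T @ Nu  # d totals_calc / d ln free, SPD
        grad = tc - t_u
        try:
            dx = np.linalg.solve(J, -grad)
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(J, -grad, rcond=None)[0]
        step_norm = np.max(np.abs(dx))
        if step_norm > 50.0:
            dx *= 50.0 / step_norm
        best = None
        t = 1.0
        for _ in range(MAX_HALVINGS):
            cand = evaluate(x + t * dx)
            # accept on decrease of either the convex potential or the
            # scaled residual norm (the latter matters near convergence,
            # where potential differences fall below float resolution)
            if (cand[2] < pot or cand[3] < res) and np.isfinite(cand[3]):
                best = (x + t * dx, cand)
                break
            t *= 0.5
        if best is None:
            break  # no descent direction left; convergence test decides
        x, (conc, tc, pot, res) = best
        converged = res <= 1.0

    free = np.zeros(nc)
    free[unknown] = np.exp(x)
    for i, val in fixed_idx.items():
        free[i] = val
    full_conc = np.zeros(model.n_species)
    expo = np.minimum(lnb_a + Nu @ x, _EXP_CLIP)
    full_conc[alive] = np.exp(expo)
    totals_calc = N.T @ full_conc
    diff = totals - totals_calc
    # fixed components have no balance requirement
    for i in fixed_idx:
        diff[i] = 0.0
    for k in zero:
        diff[k] = 0.0

    state = SpeciationState(
        free=free,
        species_conc=full_conc,
        totals_given=totals,
        totals_calc=totals_calc,
        diff=diff,
        converged=converged,
        iterations=iterations,
        T=T,
        model=model,
    )
    if not converged:
        raise SolverError(
            f"Newton-Raphson did not converge in {iterations} iterations "
            f"(max scaled residual {res:.3g})",
            state=state,
        )
    return state


def ph_of(state: SpeciationState) -> float:
    """pH = -log10 of the free proton concentration of a converged state."""
    if not state.converged:
        raise SolverError("pH requested from an unconverged state", state=state)
    if state.model.proton_index is None:
        raise ValueError("model has no proton component")
    h = state.free[state.model.proton_index]
    if h <= 0:
        raise ValueError("free proton concentration is not positive")
    return -np.log10(h)
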