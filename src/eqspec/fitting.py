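"""Global Newton-Gauss least squares for van't Hoff parameters.

The outer loop refines selected (dH, dS) entries of an equilibrium model to
minimise the sum of squared pH residuals over a (possibly multi-temperature,
multi-condition) augmented titration dataset.  Each residual evaluation runs
the inner Newton-Raphson speciation over every titration point.

Standard errors come from the usual linearised analysis at the optimum:
sigma_R = sqrt(ssq / df) with df = m - np, and sigma_P,j = sigma_R *
sqrt(((J^t J)^-1)_jj) with J = d r / d p computed by forward finite
differences.  Marquardt-style damping on the normal equations guards the
iteration; accepted steps never increase ssq.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import FitError, IdentifiabilityError, SolverError
from .model import EquilibriumModel
from .speciation import ph_of, solve_free_concentrations
from .titration import TitrationDataset

#: Internal scaling: dH is fitted in kJ/mol so both parameter kinds are O(10^2).
_SCALE = {"dh": 1e3, "ds": 1.0}

#: Relative forward-difference step for the residual Jacobian.
FD_REL_STEP = 1e-6

#: Parameter pairs with |correlation| above this are flagged as degenerate.
CORR_THRESHOLD = 0.999

# J columns that are exactly parallel analytically still differ at the
# forward-difference noise level (~1e-6), so "singular" must be read as a
# condition-number threshold.  Hard-but-identifiable built-in fits condition
# near 1e4-1e5; structurally degenerate ones near 1e7.
_COND_LIMIT = 3e5


@dataclass
class FitSpec:
    """Everything needed to run one Newton-Gauss fit."""

    model: EquilibriumModel
    dataset: TitrationDataset
    free_params: list                      # [(species_name, "dh"|"ds"), ...]
    initial_guesses: Sequence[float] | None = None  # defaults to model values
    max_iterations: int = 100
    ssq_rtol: float = 1e-9
    lm_lambda0: float = 1e-3
    lm_decrease: float = 0.1
    lm_increase: float = 10.0

    def __post_init__(self):
        norm = []
        for name, which in self.free_params:
            which = which.lower().replace("Δ", "d")
            if which not in ("dh", "ds"):
                raise FitError(f"unknown parameter kind {which!r}")
            sp = self.model[name]
            if sp.lnb_fixed is not None:
                raise FitError(f"species {name!r} has a fixed ln beta, not (dH, dS)")
            norm.append((name, which))
        self.free_params = norm

    def start_vector(self) -> np.ndarray:
        if self.initial_guesses is not None:
            p = np.asarray(self.initial_guesses, dtype=float)
            if p.shape != (len(self.free_params),):
                raise FitError("initial_guesses length mismatch")
            return p
        return np.array(
            [getattr(self.model[n], w) for n, w in self.free_params], dtype=float
        )


@dataclass
class FitResult:
    """Outcome of a Newton-Gauss fit (parameters in external units)."""

    free_params: list
    p_hat: np.ndarray
    residuals: np.ndarray
    ssq: float
    m: int
    n_params: int
    sigma_r: float | None
    sigma_p: np.ndarray | None
    correlation: np.ndarray | None
    flagged_pairs: list
    iterations: int
    converged: bool
    ssq_trace: list
    jacobian: np.ndarray | None = None
    accuracy: np.ndarray | None = None

    @property
    def df(self) -> int:
        return self.m - self.n_params

    def param_dict(self) -> dict:
        return {key: float(v) for key, v in zip(self.free_params, self.p_hat)}

    def value_of(self, species: str, which: str) -> float:
        return float(self.p_hat[self.free_params.index((species, which.lower()))])

    def sigma_of(self, species: str, which: str) -> float:
        return float(self.sigma_p[self.free_params.index((species, which.lower()))])


def _apply_params(model: EquilibriumModel, free_params, p) -> EquilibriumModel:
    updates: dict = {}
    for (name, which), val in zip(free_params, p):
        updates.setdefault(name, {})[which] = float(val)
    return model.with_thermo(updates)


def residuals(model: EquilibriumModel, p, dataset: TitrationDataset,
              free_params: Sequence | None = None) -> np.ndarray:
    """r_i = d_meas,i - d_calc,i over every block point.

    ``p`` overrides the values of ``free_params`` in the model (pass
    ``free_params=None`` with an empty ``p`` to evaluate the model as-is).
    """
    if free_params:
        model = _apply_params(model, free_params, p)
    out = []
    for block in dataset.blocks:
        guess = None
        calc = np.empty(block.n_points)
        for i in range(block.n_points):
            state = solve_free_concentrations(
                model, block.totals[i], block.T, initial_guess=guess
            )
            calc[i] = ph_of(state)
            guess = state.free.copy()
            guess[guess <= 0] = 1e-30
        out.append(block.ph - calc)
    return np.concatenate(out)


def accuracy(p_real: float, p_calc: float) -> float:
    """Signed accuracy in percent: 100 * (p_calc - p_real) / p_real.

    Under-estimates are negative.
    """
    if p_real == 0:
        raise ValueError("accuracy undefined for a zero reference value")
    return 100.0 * (p_calc - p_real) / p_real


def _fd_jacobian(model, dataset, free_params, q, scales, r0):
    """Forward-difference Jacobian of the residual vector w.r.t. scaled params."""
    m, n = len(r0), len(q)
    J = np.empty((m, n))
    for j in range(n):
        step = FD_REL_STEP * max(abs(q[j]), 1.0)
        qp = q.copy()
        qp[j] += step
        rp = residuals(model, qp * scales, dataset, free_params)
        J[:, j] = (rp - r0) / step
    return J


def _covariance(J, ssq, df):
    """(J^t J)^-1, sigma_R, correlation matrix and degenerate pairs via SVD."""
    U, s, Vt = np.linalg.svd(J, full_matrices=False)
    n = J.shape[1]
    if s[0] == 0:
        raise IdentifiabilityError("zero Jacobian")
    rank_deficient = s[-1] == 0 or s[0] / s[-1] > _COND_LIMIT
    if rank_deficient:
        null = Vt[-1]
        involved = [i for i in range(n) if abs(null[i]) > 0.1]
        corr = np.eye(n)
        for i in involved:
            for j in involved:
                if i != j:
                    corr[i, j] = -np.sign(null[i] * null[j])
        return None, None, corr, involved
    hinv = (Vt.T / s**2) @ Vt
    sigma_r = float(np.sqrt(ssq / df)) if df > 0 else None
    d = np.sqrt(np.diag(hinv))
    corr = hinv / np.outer(d, d)
    return hinv, sigma_r, corr, []


def newton_gauss_fit(spec: FitSpec, truth: Sequence[float] | None = None) -> FitResult:
    """Damped Newton-Gauss minimisation of ssq over the free parameters.

    Parameters are scaled internally (dH in kJ/mol) so the normal equations
    are well conditioned.  A Marquardt multiplier on the diagonal rescues
    rejected steps; the accepted-step ssq sequence is non-increasing.

    ``truth`` (generating values, external units) enables the signed
    accuracy column of the result.
    """
    free_params = spec.free_params
    n = len(free_params)
    scales = np.array([_SCALE[w] for _, w in free_params])
    p = spec.start_vector()
    q = p / scales

    m = spec.dataset.m
    df = m - n
    if df <= 0:
        raise FitError(f"degrees of freedom not positive (m={m}, np={n})")

    try:
        r = residuals(spec.model, q * scales, spec.dataset, free_params)
    except SolverError as exc:
        raise FitError(f"speciation failed at the initial guess: {exc}") from exc
    ssq = float(r @ r)
    trace = [ssq]
    lam = spec.lm_lambda0
    converged = False
    iterations = 0
    J = None

    while iterations < spec.max_iterations:
        iterations += 1
        J = _fd_jacobian(spec.model, spec.dataset, free_params, q, scales, r)
        JtJ = J.T @ J
        Jtr = J.T @ r
        diag = np.diag(JtJ).copy()
        diag[diag == 0] = 1.0
        accepted = False
        for _ in range(60):
            try:
                dq = -np.linalg.solve(JtJ + lam * np.diag(diag), Jtr)
            except np.linalg.LinAlgError:
                lam *= spec.lm_increase
                continue
            q_try = q + dq
            try:
                r_try = residuals(spec.model, q_try * scales, spec.dataset, free_params)
            except SolverError:
                lam *= spec.lm_increase
                continue
            ssq_try = float(r_try @ r_try)
            if np.isfinite(ssq_try) and ssq_try <= ssq:
                accepted = True
                break
            lam *= spec.lm_increase
        if not accepted:
            break
        rel_drop = (ssq - ssq_try) / max(ssq, 1e-300)
        q, r, ssq = q_try, r_try, ssq_try
        trace.append(ssq)
        lam = max(lam * spec.lm_decrease, 1e-14)
        if rel_drop < spec.ssq_rtol:
            converged = True
            break

    # statistics from the undamped normal equations at the solution
    if J is None:
        J = _fd_jacobian(spec.model, spec.dataset, free_params, q, scales, r)
    hinv, sigma_r_scaled, corr, involved = _covariance(J, ssq, df)
    p_hat = q * scales
    if hinv is not None and sigma_r_scaled is not None:
        sigma_q = sigma_r_scaled * np.sqrt(np.diag(hinv))
        sigma_p = sigma_q * scales
    else:
        sigma_p = None
    flagged = _flag_pairs(free_params, corr, spec.model)
    acc = None
    if truth is not None:
        acc = np.array([accuracy(t, v) for t, v in zip(truth, p_hat)])
    return FitResult(
        free_params=list(free_params),
        p_hat=p_hat,
        residuals=r,
        ssq=ssq,
        m=m,
        n_params=n,
        sigma_r=sigma_r_scaled,
        sigma_p=sigma_p,
        correlation=corr,
        flagged_pairs=flagged,
        iterations=iterations,
        converged=converged,
        ssq_trace=trace,
        jacobian=J,
        accuracy=acc,
    )


def _flag_pairs(free_params, corr, model) -> list:
    flagged = []
    if corr is None:
        return flagged
    n = len(free_params)
    structural = {frozenset(s) for s in model.correlated_sets}
    for i in range(n):
        for j in range(i + 1, n):
            high = abs(corr[i, j]) > CORR_THRESHOLD
            same_stoich = any(
                free_params[i][0] in s and free_params[j][0] in s
                and free_params[i][0] != free_params[j][0]
                for s in structural
            )
            if high:
                flagged.append((free_params[i], free_params[j],
                                float(corr[i, j]), same_stoich))
    return flagged


def parameter_errors(result: FitResult) -> np.ndarray:
    """sigma_P per parameter from the stored Jacobian: sigma_R*sqrt(H^-1_jj)."""
    if result.df <= 0:
        raise FitError("no degrees of freedom")
    if result.jacobian is None:
        raise FitError("result carries no Jacobian")
    hinv, sigma_r, corr, involved = _covariance(result.jacobian, result.ssq, result.df)
    if hinv is None:
        names = [result.free_params[i] for i in involved]
        raise IdentifiabilityError(
            f"singular normal equations; correlated parameters: {names}",
            correlated=names,
        )
    scales = np.array([_SCALE[w] for _, w in result.free_params])
    return sigma_r * np.sqrt(np.diag(hinv)) * scales


def correlation_diagnostics(result: FitResult) -> tuple:
    """(correlation matrix, flagged pairs) of the fitted parameters."""
    return result.correlation, result.flagged_pairs
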