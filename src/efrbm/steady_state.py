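"""Steady-state solvers for the EFRBM.

For ``q, r > 0`` the model is contractive (after a small overshoot) with
respect to the L1 norm, so a unique, globally asymptotically stable steady
state ``e ∈ (0,1)^n`` exists.  At ``e`` all inter-site flows agree,
``R = g_0(e) = ... = g_n(e)``, defining the steady throughput ``R``.

The primary solver is a damped Newton iteration on ``f(e) = 0`` with the
analytic Jacobian, backtracking to keep iterates inside the open unit cube.
Integrate-to-convergence is the fallback, and for ``n = 2`` under the
thermodynamic coupling ``q = 1/r`` the exact closed form (a single
quadratic) is available.

A caveat discovered empirically: for sufficiently strong attachment
interactions (large ``q``) the vector field can carry *several* interior
equilibria, more than one of them locally stable (e.g. three equilibria at
``n = 6``, unit rates, ``r = 0.1``, ``q = 10``).  The uniqueness guarantee
is therefore treated as holding for moderate interactions only.  To return
a physically meaningful answer everywhere, :func:`solve` verifies that the
root it found is linearly stable (Hurwitz Jacobian) and, when Newton lands
on an unstable equilibrium, falls back to the attractor reached by the flow
from the canonical interior start ``0.5·1_n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .model import (
    EFRBMParams,
    DegenerateInteractionWarning,
    flows,
    vector_field,
    vector_field_jacobian,
)

__all__ = [
    "SteadyStateResult",
    "ConvergenceError",
    "solve",
    "closed_form_n2",
    "homogeneity_check",
    "flow_bound_check",
]


class ConvergenceError(RuntimeError):
    """No steady state located to the requested tolerance."""


@dataclass(frozen=True)
class SteadyStateResult:
    """Steady state of an EFRBM.

    Attributes
    ----------
    e
        Steady densities, componentwise in ``(0, 1)`` when ``q, r > 0``.
    R
        Steady flow (1/time): the common value of all inter-site flows.
    residual
        ``max_i |g_i(e) - R|``, the violation of the flow-equality chain.
    method
        ``"newton"``, ``"integrate"`` or ``"closed_form_n2"``.
    converged
        Whether the stationarity tolerance was met.
    warnings
        Diagnostics, e.g. a non-uniqueness flag when ``q*r = 0``.
    """

    e: NDArray[np.float64]
    R: float
    residual: float
    method: str
    converged: bool
    warnings: tuple[str, ...] = ()
    n_iter: int = 0

    @property
    def total_occupancy(self) -> float:
        return float(np.sum(self.e))

    def rounded(self, decimals: int = 4) -> "SteadyStateResult":
        """Copy with densities and flow rounded for reporting (results are
        conventionally quoted to four digits)."""
        return SteadyStateResult(
            e=np.round(self.e, decimals),
            R=round(self.R, decimals),
            residual=self.residual,
            method=self.method,
            converged=self.converged,
            warnings=self.warnings,
            n_iter=self.n_iter,
        )


def _result(p: EFRBMParams, e: NDArray[np.float64], method: str, tol: float,
            n_iter: int, extra_warnings: tuple[str, ...] = ()) -> SteadyStateResult:
    g = flows(p, e)
    R = float(g[-1])
    residual = float(np.max(np.abs(g - R)))
    f_inf = float(np.max(np.abs(vector_field(p, e))))
    return SteadyStateResult(
        e=e,
        R=R,
        residual=residual,
        method=method,
        converged=f_inf < tol,
        warnings=extra_warnings,
        n_iter=n_iter,
    )


def _newton(p: EFRBMParams, x0: NDArray[np.float64], tol: float,
            max_iter: int = 200) -> tuple[NDArray[np.float64], int, bool]:
    """Damped Newton on the vector field, constrained to the open cube."""
    x = np.clip(np.asarray(x0, dtype=float), 1e-12, 1.0 - 1e-12)
    f = vector_field(p, x)
    norm = np.max(np.abs(f))
    for it in range(1, max_iter + 1):
        if norm < tol:
            return x, it - 1, True
        J = vector_field_jacobian(p, x)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return x, it - 1, False
        alpha = 1.0
        for _ in range(60):
            x_new = x + alpha * step
            if np.all(x_new > 0.0) and np.all(x_new < 1.0):
                f_new = vector_field(p, x_new)
                norm_new = np.max(np.abs(f_new))
                if norm_new < (1.0 - 1e-4 * alpha) * norm or norm_new < tol:
                    x, f, norm = x_new, f_new, norm_new
                    break
            alpha *= 0.5
        else:
            return x, it, False
    return x, max_iter, norm < tol


def _continuation_newton(p: EFRBMParams, tol: float,
                         n_steps: int = 12) -> tuple[NDArray[np.float64], bool]:
    """Homotopy in the interaction parameters: walk (r, q) geometrically
    from the RFM point (1, 1) — where Newton from 0.5·1_n is reliable — to
    the target, warm-starting each solve.  Rescues Newton at extreme
    interactions, where densities sit close to the cube boundary."""
    x = np.full(p.n, 0.5)
    for k in range(1, n_steps + 1):
        frac = k / n_steps
        pk = EFRBMParams(lambdas=p.lambdas, r=p.r**frac, q=p.q**frac)
        x, _, ok = _newton(pk, x, tol)
        if not ok:
            return x, False
    return x, True


def _integrate_to_equilibrium(p: EFRBMParams, x0: NDArray[np.float64], tol: float,
                              t_cap: float = 1e4) -> tuple[NDArray[np.float64], bool]:
    """Follow the flow until ``|f|_∞ < tol`` or the time cap — correct for
    any ``q, r > 0`` by global asymptotic stability; the cap guards the
    degenerate ``q*r = 0`` inputs where convergence is not guaranteed."""
    from scipy.integrate import solve_ivp

    x = np.clip(np.asarray(x0, dtype=float), 0.0, 1.0)
    t, chunk = 0.0, 10.0
    while t < t_cap:
        sol = solve_ivp(
            lambda _t, y: vector_field(p, y),
            (0.0, chunk),
            x,
            method="LSODA",
            jac=lambda _t, y: vector_field_jacobian(p, y),
            rtol=1e-12,
            atol=1e-13,
        )
        if not sol.success:
            return x, False
        x = sol.y[:, -1]
        t += chunk
        if np.max(np.abs(vector_field(p, x))) < tol:
            return x, True
        chunk = min(2.0 * chunk, t_cap - t) or chunk
    return x, np.max(np.abs(vector_field(p, x))) < tol


def solve(p: EFRBMParams, tol: float = 1e-12, x0: ArrayLike | None = None,
          method: str = "auto") -> SteadyStateResult:
    """Compute the steady state ``e`` and steady flow ``R``.

    Parameters
    ----------
    p
        Model parameters.  ``q, r > 0`` guarantees a unique interior
        solution; with ``q*r = 0`` an equilibrium is still sought by
        integration but flagged as possibly non-unique.
    tol
        Stationarity tolerance on ``|f(e)|_∞``.
    x0
        Optional initial guess (used to warm-start continuation sweeps).
    method
        ``"newton"``, ``"integrate"`` or ``"auto"`` (Newton with
        integration fallback, plus a second-start uniqueness check).

    Raises
    ------
    ConvergenceError
        If no equilibrium is found to tolerance; never returns a silent
        partial answer.
    """
    extra: list[str] = []
    if p.q * p.r == 0.0:
        # Jacobian may be singular on the attracting set: integrate only.
        x_start = np.full(p.n, 0.5) if x0 is None else np.asarray(x0, float)
        e, ok = _integrate_to_equilibrium(p, x_start, tol)
        if not ok:
            raise ConvergenceError(
                "integration did not reach an equilibrium (q*r = 0: none may exist "
                "or a continuum may be approached arbitrarily slowly)"
            )
        smin = float(np.linalg.svd(vector_field_jacobian(p, e), compute_uv=False)[-1])
        extra.append("uniqueness not guaranteed (q*r = 0); "
                     f"smallest Jacobian singular value at solution: {smin:.3e}")
        return _result(p, e, "integrate", tol, 0, tuple(extra))

    if method not in {"auto", "newton", "integrate"}:
        raise ValueError(f"unknown method {method!r}")

    if method == "integrate":
        x_start = np.full(p.n, 0.5) if x0 is None else np.asarray(x0, float)
        e, ok = _integrate_to_equilibrium(p, x_start, tol)
        if ok:
            e_p, n_it, ok_p = _newton(p, e, tol)  # polish to full precision
            if ok_p and np.max(np.abs(e_p - e)) < 1e-6:
                e = e_p
        if not ok:
            raise ConvergenceError("integration did not converge to tolerance")
        return _result(p, e, "integrate", tol, 0, tuple(extra))

    guess = np.full(p.n, 0.5) if x0 is None else np.clip(np.asarray(x0, float), 1e-9, 1 - 1e-9)
    e, n_iter, ok = _newton(p, guess, tol)
    used = "newton"
    if ok and not _is_stable(p, e):
        # Newton can land on a non-attracting root when the model is
        # multistable; the physically relevant state is an attractor.
        extra.append("Newton converged to an unstable equilibrium; "
                     "switched to the attractor reached from the canonical start")
        ok = False
    if not ok:
        if method == "newton":
            raise ConvergenceError(
                "Newton iteration failed to locate a stable equilibrium"
            )
        e, ok = _continuation_newton(p, tol)
        if ok and _is_stable(p, e):
            used = "newton"
        else:
            e, ok = _integrate_to_equilibrium(
                p, np.full(p.n, 0.5) if x0 is None else guess, tol
            )
            if not ok:
                raise ConvergenceError("Newton and integration both failed to converge")
            e_p, n_iter, ok_p = _newton(p, e, tol)
            if ok_p and np.max(np.abs(e_p - e)) < 1e-6:
                e = e_p
            used = "integrate"

    if method == "auto" and x0 is None:
        # verify independence of the starting point (uniqueness cross-check)
        alt = 0.2 + 0.6 * (np.arange(p.n) % 2)
        e2, _, ok2 = _newton(p, alt, tol)
        if ok2 and _is_stable(p, e2) and np.max(np.abs(e2 - e)) > 1e3 * max(tol, 1e-12) + 1e-8:
            extra.append(
                "multiple stable equilibria detected: a second Newton start found "
                f"a distinct root (max density gap {np.max(np.abs(e2 - e)):.2e}); "
                "returning the attractor of the canonical interior start"
            )
            e_c, ok_c = _integrate_to_equilibrium(p, np.full(p.n, 0.5), tol)
            if ok_c:
                e_p, _, ok_p = _newton(p, e_c, tol)
                e = e_p if ok_p and np.max(np.abs(e_p - e_c)) < 1e-6 else e_c
                used = "integrate"
    return _result(p, e, used, tol, n_iter, tuple(extra))


def _is_stable(p: EFRBMParams, e: NDArray[np.float64], tol: float = 1e-9) -> bool:
    """Linear stability of an equilibrium (Hurwitz Jacobian).  One
    eigenvalue can sit at zero only in degenerate (q*r = 0) cases, so a
    small positive slack suffices."""
    eig = np.linalg.eigvals(vector_field_jacobian(p, e))
    return bool(np.max(eig.real) < tol)


def closed_form_n2(p: EFRBMParams) -> SteadyStateResult:
    """Exact steady state for ``n = 2`` under the coupling ``q = 1/r``.

    With ``a_1 = (1 - 1/r)(λ_2 r + λ_1) + λ_1 λ_2 / λ_0`` the density at
    site 2 solves ``a_1 e_2² - (λ_1 + λ_2 + a_1) e_2 + λ_1 = 0``; the
    feasible root (both densities in ``(0,1)``) is

    ``e_2 = (λ_1 + λ_2 + a_1 - sqrt((λ_1 + λ_2 + a_1)² - 4 a_1 λ_1)) / (2 a_1)``

    and ``e_1 = λ_2 e_2 / (λ_1 + (λ_2 (1 - r) - λ_1) e_2)``.  For ``r = 1``
    the first term of ``a_1`` vanishes and ``a_1 = λ_1 λ_2 / λ_0`` (the RFM
    case); no special handling is needed.
    """
    if p.n != 2:
        raise ValueError(f"closed form applies to n=2 only, got n={p.n}")
    if not p.r > 0:
        raise ValueError("closed form requires r > 0")
    if abs(p.q * p.r - 1.0) > 1e-9:
        raise ValueError("closed form assumes the thermodynamic coupling q = 1/r")
    lam0, lam1, lam2 = p.lambdas
    r = p.r
    a1 = (1.0 - 1.0 / r) * (lam2 * r + lam1) + lam1 * lam2 / lam0
    s = lam1 + lam2 + a1  # = -a2 of the quadratic a1 e² + a2 e + λ1 = 0

    def _e1(e2: float) -> float:
        return lam2 * e2 / (lam1 + (lam2 * (1.0 - r) - lam1) * e2)

    if a1 == 0.0:
        e2 = lam1 / s  # quadratic degenerates to -s e2 + λ1 = 0
    else:
        disc = s * s - 4.0 * a1 * lam1
        if disc < 0:
            raise ConvergenceError("negative discriminant in the n=2 closed form")
        root = float(np.sqrt(disc))
        e2 = (s - root) / (2.0 * a1)
        if not (0.0 < e2 < 1.0 and 0.0 < _e1(e2) < 1.0):
            e2_other = (s + root) / (2.0 * a1)
            if 0.0 < e2_other < 1.0 and 0.0 < _e1(e2_other) < 1.0:
                raise ConvergenceError(
                    "the printed quadratic root is infeasible while the other root "
                    f"is feasible (r={r}, a1={a1}); refusing to swap silently"
                )
            raise ConvergenceError(f"no feasible root of the n=2 quadratic (r={r})")
    e = np.array([_e1(e2), e2], dtype=float)
    return _result(p, e, "closed_form_n2", tol=1e-10, n_iter=0)


def homogeneity_check(p: EFRBMParams, c: float, tol: float = 1e-12) -> tuple[float, float]:
    """Degree-0/degree-1 homogeneity of the steady state in the rates.

    Scaling every rate by ``c > 0`` only rescales time, so the steady
    densities are unchanged while the flow scales linearly:
    ``e(cλ) = e(λ)`` and ``R(cλ) = c R(λ)``.

    Returns
    -------
    (density_shift, flow_ratio)
        ``|e(cλ) - e(λ)|_∞`` (expected ~0) and ``R(cλ)/R(λ)``
        (expected ``c``).
    """
    if not c > 0:
        raise ValueError("scale factor must be positive")
    base = solve(p, tol=tol)
    scaled = solve(p.scaled(c), tol=tol * c, x0=base.e)
    shift = float(np.max(np.abs(scaled.e - base.e)))
    return shift, scaled.R / base.R


def flow_bound_check(res: SteadyStateResult, p: EFRBMParams, slack: float = 1e-12) -> bool:
    """Check the throughput bound ``R <= max(λ_0, λ_n)`` (thermodynamic
    coupling ``q = 1/r``).  Returns True on *violation*."""
    bound = max(float(p.lambdas[0]), float(p.lambdas[-1]))
    return bool(res.R > bound + slack)
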