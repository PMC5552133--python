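"""Parameter sweeps, jam diagnostics, contraction fits and sensitivities.

These are the numerical experiments behind the model's phenomenology: how
the steady flow and density profile respond to the interaction strength
``r`` (with ``q = 1/r``), how strongly two trajectories contract toward
each other, and how the steady state moves under small parameter changes
(well defined because the steady state is an analytic function of the
positive parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .model import EFRBMParams
from .steady_state import ConvergenceError, SteadyStateResult, solve

__all__ = [
    "SweepResult",
    "ContractionEstimate",
    "JamMetrics",
    "sweep_r",
    "jam_metrics",
    "contraction_estimate",
    "sensitivity",
]


@dataclass(frozen=True)
class SweepResult:
    """Steady-state response along a grid of interaction strengths.

    ``e_profiles[k]`` is the density profile at ``r_grid[k]``; failed grid
    points carry NaN rows and an entry in ``failures``.
    """

    r_grid: NDArray[np.float64]
    R_values: NDArray[np.float64]
    e_profiles: NDArray[np.float64]  # shape (len(grid), n)
    failures: tuple[tuple[int, str], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        n = self.e_profiles.shape[1]
        data = {"r": self.r_grid, "R": self.R_values}
        for i in range(n):
            data[f"e{i + 1}"] = self.e_profiles[:, i]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ContractionEstimate:
    """Fitted exponential envelope of an L1 trajectory-distance curve.

    The model contracts after a small overshoot: the distance is dominated
    by ``(1 + eps) e^{-ell t} d(0)``.  ``ell`` is the decay rate fitted by
    least squares on log-distance over ``fit_window`` (the tail, to exclude
    the permitted transient); ``eps`` is the smallest overshoot making the
    envelope dominate the *whole* measured curve; ``r2`` the fit quality.
    """

    ell: float
    eps: float
    fit_window: tuple[float, float]
    r2: float

    def envelope(self, t, d0: float):
        return (1.0 + self.eps) * d0 * np.exp(-self.ell * np.asarray(t))


@dataclass(frozen=True)
class JamMetrics:
    """Occupancy summary of a steady profile: a jam shows as a large total
    occupancy with near-unit upstream densities, density separation as a
    tiny maximum over even-indexed sites."""

    total_occupancy: float
    max_density: float
    argmax_site: int  # 1-based
    even_site_max: float


def sweep_r(
    p_base: EFRBMParams,
    r_grid,
    couple_q: bool = True,
    tol: float = 1e-12,
    warm_start: bool = True,
) -> SweepResult:
    """Solve the steady state along a grid of ``r`` values.

    With ``couple_q`` the thermodynamic constraint ``q = 1/r`` is applied at
    each point; otherwise ``q`` is held at ``p_base.q``.  Consecutive solves
    are warm-started from the previous profile (the steady state is
    continuous in ``r``), which keeps Newton in its quadratic regime across
    decades of ``r``.  Per-point failures are recorded and the sweep
    continues.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0):
        raise ValueError("r grid must be positive")
    n = p_base.n
    R_values = np.full(r_grid.size, np.nan)
    e_profiles = np.full((r_grid.size, n), np.nan)
    failures: list[tuple[int, str]] = []
    x0 = None
    for k, r in enumerate(r_grid):
        q = 1.0 / r if couple_q else p_base.q
        p = EFRBMParams(lambdas=p_base.lambdas, r=float(r), q=q)
        try:
            res = solve(p, tol=tol, x0=x0 if warm_start else None)
        except ConvergenceError as exc:
            failures.append((k, str(exc)))
            x0 = None
            continue
        R_values[k] = res.R
        e_profiles[k] = res.e
        x0 = res.e
    return SweepResult(
        r_grid=r_grid, R_values=R_values, e_profiles=e_profiles,
        failures=tuple(failures),
    )


def jam_metrics(res: SteadyStateResult) -> JamMetrics:
    """Occupancy diagnostics of a converged steady state."""
    if not res.converged:
        raise ValueError("jam metrics require a converged steady-state result")
    e = res.e
    k = int(np.argmax(e))
    even = e[1::2]  # sites 2, 4, ...
    return JamMetrics(
        total_occupancy=float(np.sum(e)),
        max_density=float(e[k]),
        argmax_site=k + 1,
        even_site_max=float(np.max(even)) if even.size else 0.0,
    )


def contraction_estimate(curve, tail_fraction: float = 0.7) -> ContractionEstimate:
    """Fit the contraction envelope ``(1+ε) e^{-ℓt} d(0)`` to a measured
    L1 distance curve.

    The decay rate is fitted on the trailing ``tail_fraction`` of the curve
    (log-distance vs. time, least squares) so the permitted early overshoot
    does not bias ``ℓ``; points at numerical zero are dropped before taking
    logs.  The overshoot ``ε = max(0, max_t d(t) e^{ℓt}/d(0) - 1)`` is then
    the smallest prefactor that makes the envelope dominate everywhere.
    """
    arr = np.asarray(list(curve), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 10:
        raise ValueError("curve must contain at least 10 (time, distance) pairs")
    t, d = arr[:, 0], arr[:, 1]
    d0 = d[0]
    if d0 <= 0:
        raise ValueError("initial distance must be positive (distinct start points)")
    floor = max(1e-14, 1e-12 * d0)
    keep = d > floor
    start = int(np.searchsorted(t, t[0] + (1.0 - tail_fraction) * (t[-1] - t[0])))
    window = keep.copy()
    window[:start] = False
    if window.sum() < 3:
        window = keep  # distance underflowed early: fit wherever it is finite
        if window.sum() < 3:
            raise ValueError("too few nonzero distances to fit a decay rate")
    tw, logd = t[window], np.log(d[window])
    slope, intercept = np.polyfit(tw, logd, 1)
    resid = logd - (slope * tw + intercept)
    ss_tot = float(np.sum((logd - logd.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    ell = max(-float(slope), 0.0)
    eps = max(0.0, float(np.max(d * np.exp(ell * t))) / d0 - 1.0)
    return ContractionEstimate(
        ell=ell, eps=eps, fit_window=(float(tw[0]), float(tw[-1])), r2=r2,
    )


_PARAM_IDS = ("r", "q")


def sensitivity(
    p: EFRBMParams, param_id: str, h: float | None = None, tol: float = 1e-12
) -> tuple[float, NDArray[np.float64]]:
    """Central-difference sensitivity of the steady state.

    ``param_id`` is ``"lambda0" .. "lambda<n>"``, ``"r"`` or ``"q"``.
    Returns ``(∂R/∂v, ∂e/∂v)``.  The steady state is an analytic function
    of the positive parameters, so central differences with
    ``h = 1e-6 max(1, |v|)`` are accurate away from ``q·r = 0``.
    """
    if param_id in _PARAM_IDS:
        v = getattr(p, param_id)
    elif param_id.startswith("lambda"):
        idx = int(param_id[len("lambda"):])
        if not 0 <= idx <= p.n:
            raise ValueError(f"rate index out of range in {param_id!r}")
        v = float(p.lambdas[idx])
    else:
        raise ValueError(f"unknown parameter {param_id!r}")
    if h is None:
        h = 1e-6 * max(1.0, abs(v))
    if h > 0.1 * abs(v):
        raise ValueError(f"step h={h} exceeds 10% of |{param_id}|={abs(v)}")

    def perturbed(delta: float) -> EFRBMParams:
        if param_id == "r":
            return EFRBMParams(lambdas=p.lambdas, r=p.r + delta, q=p.q)
        if param_id == "q":
            return EFRBMParams(lambdas=p.lambdas, r=p.r, q=p.q + delta)
        lam = p.lambdas.copy()
        lam[idx] += delta
        return EFRBMParams(lambdas=lam, r=p.r, q=p.q)

    base = solve(p, tol=tol)
    plus = solve(perturbed(+h), tol=tol, x0=base.e)
    minus = solve(perturbed(-h), tol=tol, x0=base.e)
    dR = (plus.R - minus.R) / (2.0 * h)
    de = (plus.e - minus.e) / (2.0 * h)
    return float(dR), de
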