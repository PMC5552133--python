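"""Extreme-interaction expansions under the thermodynamic coupling q = 1/r.

Two regimes bracket the physics:

* ``r -> 0`` (strong binding to existing neighbors, strong attraction to
  new ones): particles pile up at the lattice start — a traffic jam — and
  the throughput collapses linearly, ``R = O(r)``.
* ``r -> ∞`` (strong repulsion between neighbors, expansion variable
  ``q = 1/r -> 0``): every second site empties — "separation of densities",
  the opposite of a jam — and the throughput saturates at a positive limit.

Closed-form Taylor coefficients are available for ``n = 2`` and ``n = 3``;
the ``n = 3`` large-``r`` leading order requires solving a small limiting
balance system that has no closed form, handled numerically here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import EFRBMParams
from .steady_state import closed_form_n2, solve

__all__ = [
    "ExpansionCoefficients",
    "small_r_n2",
    "small_r_n3",
    "large_r_n2",
    "large_r_n3",
    "large_r_n3_first_order",
    "expansion_error_curve",
]


@dataclass(frozen=True)
class ExpansionCoefficients:
    """Taylor coefficients of one steady density near an extreme limit:
    ``e_site(ε) = a + b ε + c ε² + o(ε^order)`` where ``ε`` is ``r``
    (jam regime) or ``q`` (separation regime) and ``order`` is the highest
    order whose coefficient is known (``None`` entries beyond it)."""

    site: int
    a: float
    b: float | None = None
    c: float | None = None
    variable: str = "r"

    @property
    def order(self) -> int:
        if self.c is not None:
            return 2
        if self.b is not None:
            return 1
        return 0

    def __call__(self, eps: float) -> float:
        """Evaluate the truncated expansion at ``ε = eps``."""
        val = self.a
        if self.b is not None:
            val += self.b * eps
        if self.c is not None:
            val += self.c * eps * eps
        return val


def _require(p: EFRBMParams, n: int) -> None:
    if p.n != n:
        raise ValueError(f"expansion defined for n={n}, got n={p.n}")


def small_r_n2(p: EFRBMParams) -> tuple[list[ExpansionCoefficients], float]:
    """Jam-regime expansion for ``n = 2``:
    ``e_1 = 1 + o(r)``, ``e_2 = 1 - (λ_2/λ_1) r + o(r)`` and
    ``R = λ_2 r + o(r)`` (slope returned as the second element)."""
    _require(p, 2)
    lam = p.lambdas
    coeffs = [
        ExpansionCoefficients(site=1, a=1.0, b=0.0, variable="r"),
        ExpansionCoefficients(site=2, a=1.0, b=-lam[2] / lam[1], variable="r"),
    ]
    return coeffs, float(lam[2])


def small_r_n3(p: EFRBMParams) -> tuple[list[ExpansionCoefficients], float]:
    """Jam-regime expansion for ``n = 3``:

    ``e_1 = 1 - λ_2 λ_3 / (λ_0 (λ_2 + λ_3)) r² + o(r²)``,
    ``e_2 = 1 - (λ_3/λ_1) r² + o(r²)``,
    ``e_3 = λ_2 / (λ_2 + λ_3) + o(r)``  (first-order coefficient unknown),
    ``R = λ_2 λ_3 / (λ_2 + λ_3) r + o(r)``.
    """
    _require(p, 3)
    lam = p.lambdas
    denom = lam[2] + lam[3]
    coeffs = [
        ExpansionCoefficients(site=1, a=1.0, b=0.0, c=-lam[2] * lam[3] / (lam[0] * denom),
                              variable="r"),
        ExpansionCoefficients(site=2, a=1.0, b=0.0, c=-lam[3] / lam[1], variable="r"),
        ExpansionCoefficients(site=3, a=lam[2] / denom, variable="r"),
    ]
    return coeffs, float(lam[2] * lam[3] / denom)


def large_r_n2(p: EFRBMParams) -> tuple[list[ExpansionCoefficients], float]:
    """Separation-regime expansion for ``n = 2`` in ``q = 1/r``:
    ``e_1 = λ_0/(λ_0 + λ_1) + o(q)``, ``e_2 = (λ_1/λ_2) q + o(q)``,
    ``R(r → ∞) = λ_0 λ_1 / (λ_0 + λ_1)`` (limit returned second)."""
    _require(p, 2)
    lam = p.lambdas
    coeffs = [
        ExpansionCoefficients(site=1, a=lam[0] / (lam[0] + lam[1]), variable="q"),
        ExpansionCoefficients(site=2, a=0.0, b=lam[1] / lam[2], variable="q"),
    ]
    return coeffs, float(lam[0] * lam[1] / (lam[0] + lam[1]))


def _limiting_balance_n3(lam: np.ndarray) -> tuple[float, float]:
    """Leading densities (a1, a3) of the n=3 separation regime.

    Matching orders in the steady-flow chain as q -> 0 gives the balance

        λ0 (1 - a1) = λ1 a1 (1 - a3) = λ3 a3 (1 + λ1/λ2),

    with a unique solution a1, a3 in (0,1).  Eliminate a3 via the outer
    equality and bracket a1 on (0,1).
    """
    lam0, lam1, lam2, lam3 = lam
    kappa = lam3 * (1.0 + lam1 / lam2)

    def a3_of(a1: float) -> float:
        return lam0 * (1.0 - a1) / kappa

    def h(a1: float) -> float:
        return lam0 * (1.0 - a1) - lam1 * a1 * (1.0 - a3_of(a1))

    # h(0) = λ0 > 0; h(1) = -λ1 < 0 → a bracketing root exists in (0,1)
    lo, hi = 1e-14, 1.0 - 1e-14
    if not (h(lo) > 0 > h(hi)):
        raise RuntimeError("failed to bracket the limiting-balance root for a1")
    a1 = float(brentq(h, lo, hi, xtol=1e-15, rtol=8.9e-16))
    a3 = float(a3_of(a1))
    return a1, a3


def large_r_n3(p: EFRBMParams) -> tuple[list[ExpansionCoefficients], float]:
    """Separation-regime expansion for ``n = 3`` in ``q = 1/r``:
    ``e_1 = a_1 + o(1)``, ``e_2 = (λ_1/λ_2) q + o(q)``, ``e_3 = a_3 + o(1)``
    with ``a_1, a_3 ∈ (0,1)`` from the limiting balance system, and
    ``R(r → ∞) = λ_0 (1 - a_1)``.

    The first-order coefficients ``b_1, b_3`` (and the O(q) flow
    correction) have no closed form; see
    :func:`large_r_n3_first_order` for their numerical extraction.
    """
    _require(p, 3)
    lam = p.lambdas
    a1, a3 = _limiting_balance_n3(lam)
    coeffs = [
        ExpansionCoefficients(site=1, a=a1, variable="q"),
        ExpansionCoefficients(site=2, a=0.0, b=lam[1] / lam[2], variable="q"),
        ExpansionCoefficients(site=3, a=a3, variable="q"),
    ]
    return coeffs, float(lam[0] * (1.0 - a1))


def large_r_n3_first_order(p: EFRBMParams, q_ref: float = 1e-4) -> tuple[float, float]:
    """Numerical first-order coefficients ``(b_1, b_3)`` of the ``n = 3``
    separation-regime densities, by Richardson extrapolation of the exact
    steady state: ``b ≈ 2 Δ(q/2) - Δ(q)`` with ``Δ(q) = (e(q) - a)/q``."""
    _require(p, 3)
    coeffs, _ = large_r_n3(p)
    a1, a3 = coeffs[0].a, coeffs[2].a

    def delta(q: float) -> tuple[float, float]:
        res = solve(EFRBMParams(lambdas=p.lambdas, r=1.0 / q, q=q))
        return (res.e[0] - a1) / q, (res.e[2] - a3) / q

    d1, d3 = delta(q_ref)
    d1h, d3h = delta(q_ref / 2.0)
    return 2.0 * d1h - d1, 2.0 * d3h - d3


_EXPANSIONS = {
    "small_r_n2": (small_r_n2, "r", 2),
    "small_r_n3": (small_r_n3, "r", 3),
    "large_r_n2": (large_r_n2, "q", 2),
    "large_r_n3": (large_r_n3, "q", 3),
}


def expansion_error_curve(
    p: EFRBMParams, which: str, eps_grid=None
) -> pd.DataFrame:
    """Empirical remainder of a truncated expansion against the exact
    steady state.

    For each ``ε`` on the grid the model is solved exactly at ``r = ε``
    (jam regime) or ``r = 1/ε`` (separation regime, ``ε = q``) and compared
    with the truncated series.  Returns a frame indexed by ``eps`` with one
    absolute-error column per site (``e1..en``) plus ``R``; the log-log
    slope of each column should exceed the truncation order of that site.

    The default grid is geometric, ``1e-1 .. 1e-5``; grids are capped near
    the cube boundary because the Newton conditioning degrades as densities
    approach 0 or 1.
    """
    if which not in _EXPANSIONS:
        raise ValueError(f"unknown expansion {which!r}; choose from {sorted(_EXPANSIONS)}")
    func, var, n = _EXPANSIONS[which]
    _require(p, n)
    if eps_grid is None:
        eps_grid = np.geomspace(1e-1, 1e-5, 9)
    eps_grid = np.asarray(eps_grid, dtype=float)
    if np.any(eps_grid <= 0) or np.any(np.diff(eps_grid) >= 0):
        raise ValueError("eps_grid must be positive and strictly decreasing")
    coeffs, r_coeff = func(p)
    rows = []
    x0 = None
    for eps in eps_grid:
        r = eps if var == "r" else 1.0 / eps
        res = solve(EFRBMParams.coupled(p.lambdas, r), x0=x0)
        x0 = res.e
        row = {"eps": eps}
        for c in coeffs:
            row[f"e{c.site}"] = abs(res.e[c.site - 1] - c(eps))
        if var == "r":
            row["R"] = abs(res.R - r_coeff * eps)  # R = slope·r + o(r)
        else:
            row["R"] = abs(res.R - r_coeff)  # R -> limit as q -> 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("eps")
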