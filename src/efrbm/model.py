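"""Core parameterization and flow algebra of the EFRBM.

The excluded flow with local repelling and binding model (EFRBM) describes
the unidirectional mean-field flow of particles (e.g. molecular motors on a
cytoskeletal filament) along a 1-D lattice of ``n`` sites.  The state
``x in [0,1]^n`` holds the normalized density at each site.  Transport obeys
a *soft* exclusion principle — flow into a site scales with ``1 - density``
— and two nearest-neighbor interaction parameters:

``q >= 0``
    attachment/detachment force when a hop *creates* a new neighbor pair
    (the density two sites ahead attracts for ``q > 1``, repels for
    ``q < 1``);
``r >= 0``
    attachment/detachment force when a hop *breaks* an existing neighbor
    pair (the density one site behind slows the hop for ``r < 1``).

For ``q = r = 1`` the model reduces to the ribosome flow model (RFM), the
mean-field ODE approximation of the open-boundary TASEP.

Two distinct boundary conventions coexist and are deliberately kept as pure
index functions rather than stored state:

* the *flow* convention ``x_0 = 1``, ``x_{n+1} = 0`` (full virtual source,
  empty virtual sink), used for the density/exclusion factors;
* the *interaction* padding ``z_i = x_i`` for ``1 <= i <= n`` and ``z_i = 0``
  otherwise, used for the neighbor-force factors (a virtual site exerts no
  force).

Sites are numbered ``1..n`` and rates ``0..n`` throughout the public API,
matching the standard notation of the field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "EFRBMParams",
    "ThermoSpec",
    "DegenerateInteractionWarning",
    "thermo_to_qr",
    "padded_density",
    "site_flow",
    "flows",
    "vector_field",
    "flow_jacobian",
    "vector_field_jacobian",
    "output_rate",
    "effective_rates",
]


class DegenerateInteractionWarning(UserWarning):
    """Raised when ``q*r == 0``: flows are well defined but the steady state
    need not be unique (a boundary continuum can appear, e.g. ``q=1, r=0``)."""


@dataclass(frozen=True)
class EFRBMParams:
    """Parameter set of an ``n``-site EFRBM.

    Parameters
    ----------
    lambdas
        Ordered transition rates ``λ_0 .. λ_n`` (units 1/time), ``n + 1``
        positive values: ``λ_0`` controls initiation, ``λ_n`` exit, and
        ``λ_i`` the hop from site ``i`` to ``i+1``.
    r
        Detachment force between *existing* neighbors, ``r >= 0``.
    q
        Attachment force toward *new* neighbors, ``q >= 0``.
    """

    lambdas: NDArray[np.float64]
    r: float
    q: float

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.ndim != 1 or lam.size < 2:
            raise ValueError(
                "lambdas must be a 1-D sequence of n+1 >= 2 rates (λ_0..λ_n)"
            )
        if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
            bad = [f"λ_{i}={v}" for i, v in enumerate(lam) if not (v > 0 and np.isfinite(v))]
            raise ValueError(f"all rates must be positive and finite; offending: {', '.join(bad)}")
        if not (self.r >= 0) or not np.isfinite(self.r):
            raise ValueError(f"r must be a nonnegative finite real, got {self.r}")
        if not (self.q >= 0) or not np.isfinite(self.q):
            raise ValueError(f"q must be a nonnegative finite real, got {self.q}")
        object.__setattr__(self, "lambdas", lam)
        object.__setattr__(self, "r", float(self.r))
        object.__setattr__(self, "q", float(self.q))
        if self.q * self.r == 0.0:
            warnings.warn(
                "q*r = 0: steady-state uniqueness/convergence guarantees require q, r > 0",
                DegenerateInteractionWarning,
                stacklevel=3,
            )

    @property
    def n(self) -> int:
        """Number of lattice sites."""
        return self.lambdas.size - 1

    @property
    def is_rfm(self) -> bool:
        """True when the model coincides with the plain RFM (q = r = 1)."""
        return self.q == 1.0 and self.r == 1.0

    @classmethod
    def thermodynamic(cls, lambdas: ArrayLike, E: float) -> "EFRBMParams":
        """Build parameters from an interaction energy ``E`` (in units of
        ``K_B T``), enforcing the detailed-balance constraint ``q*r = 1``."""
        q, r = thermo_to_qr(E)
        return cls(lambdas=np.asarray(lambdas, dtype=float), r=r, q=q)

    @classmethod
    def coupled(cls, lambdas: ArrayLike, r: float) -> "EFRBMParams":
        """Build parameters under the thermodynamic coupling ``q = 1/r``."""
        if not r > 0:
            raise ValueError("coupled construction requires r > 0")
        return cls(lambdas=np.asarray(lambdas, dtype=float), r=float(r), q=1.0 / float(r))

    def scaled(self, c: float) -> "EFRBMParams":
        """Return a copy with every rate multiplied by ``c > 0``."""
        if not c > 0:
            raise ValueError("scale factor must be positive")
        return EFRBMParams(lambdas=c * self.lambdas, r=self.r, q=self.q)


@dataclass(frozen=True)
class ThermoSpec:
    """Interaction energy specification.

    ``E`` is the pair interaction energy pre-divided by ``K_B T``
    (dimensionless).  Detailed balance with an even split of ``E`` between
    pair creation and pair breaking gives ``q = exp(E/2)``,
    ``r = exp(-E/2)``, hence ``q*r = 1`` exactly.  ``E > 0`` is attractive
    (``q > 1``, ``r < 1``), ``E < 0`` repulsive, ``E = 0`` the RFM.
    """

    E: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.E):
            raise ValueError(f"interaction energy must be finite, got {self.E}")

    def to_qr(self) -> tuple[float, float]:
        return thermo_to_qr(self.E)


def thermo_to_qr(E: float) -> tuple[float, float]:
    """Map an interaction energy ``E/(K_B T)`` to ``(q, r) = (e^{E/2}, e^{-E/2})``."""
    if not np.isfinite(E):
        raise ValueError(f"interaction energy must be finite, got {E}")
    half = 0.5 * float(E)
    return float(np.exp(half)), float(np.exp(-half))


def _as_state(x: ArrayLike) -> NDArray[np.float64]:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("density vector must be 1-D")
    return x


def padded_density(x: ArrayLike, i: int) -> float:
    """Interaction padding ``z_i``: ``x_i`` for ``1 <= i <= n``, else 0.

    Note this differs from the flow boundary convention, where ``x_0 = 1``:
    a virtual site carries no interacting particle, so ``z_0 = 0``.
    """
    x = _as_state(x)
    if 1 <= i <= x.size:
        return float(x[i - 1])
    return 0.0


def _padded(x: NDArray[np.float64]) -> NDArray[np.float64]:
    # zpad[j] == z_{j-1}; covers z_{-1} .. z_{n+2}
    n = x.size
    zpad = np.zeros(n + 4, dtype=x.dtype)
    zpad[2 : n + 2] = x
    return zpad


def flows(p: EFRBMParams, x: ArrayLike) -> NDArray[np.float64]:
    """All inter-site flows ``g_0(x) .. g_n(x)``.

    ``g_i = λ_i x_i (1 - x_{i+1}) (1 + (q-1) z_{i+2}) (1 + (r-1) z_{i-1})``
    with ``x_0 = 1``, ``x_{n+1} = 0`` and ``z`` the interaction padding.
    """
    x = _as_state(x)
    n = x.size
    if n != p.n:
        raise ValueError(f"state has {n} sites but parameters define n={p.n}")
    X = np.empty(n + 2, dtype=x.dtype)
    X[0] = 1.0
    X[1 : n + 1] = x
    X[n + 1] = 0.0
    zpad = _padded(x)
    i = np.arange(n + 1)
    return (
        p.lambdas
        * X[i]
        * (1.0 - X[i + 1])
        * (1.0 + (p.q - 1.0) * zpad[i + 3])  # z_{i+2}
        * (1.0 + (p.r - 1.0) * zpad[i])      # z_{i-1}
    )


def site_flow(p: EFRBMParams, x: ArrayLike, i: int) -> float:
    """Flow ``g_i(x)`` from site ``i`` to site ``i+1`` (``0 <= i <= n``)."""
    if not 0 <= i <= p.n:
        raise IndexError(f"flow index must lie in [0, n={p.n}], got {i}")
    return float(flows(p, x)[i])


def vector_field(p: EFRBMParams, x: ArrayLike) -> NDArray[np.float64]:
    """Right-hand side of the dynamics: ``dx_i/dt = g_{i-1}(x) - g_i(x)``."""
    g = flows(p, x)
    return g[:-1] - g[1:]


def output_rate(p: EFRBMParams, x: ArrayLike) -> float:
    """Instantaneous exit flow ``R = g_n(x) = λ_n x_n (1 + (r-1) z_{n-1})``.

    For ``n = 1`` the neighbor factor uses ``z_0 = 0`` and drops out.
    """
    return float(flows(p, x)[-1])


def effective_rates(p: EFRBMParams, x: ArrayLike) -> NDArray[np.float64]:
    """State-dependent rates ``η_0 .. η_n`` of the equivalent RFM form.

    ``η_i = λ_i (1 + (q-1) z_{i+2}) (1 + (r-1) z_{i-1})`` turns the model
    into an RFM with time-varying rates:
    ``dx_i/dt = η_{i-1} x_{i-1} (1 - x_i) - η_i x_i (1 - x_{i+1})``.
    Each ``η_i`` is bounded by ``min(1,q) min(1,r) λ_i`` from below and
    ``max(1,q) max(1,r) λ_i`` from above.
    """
    x = _as_state(x)
    if x.size != p.n:
        raise ValueError(f"state has {x.size} sites but parameters define n={p.n}")
    zpad = _padded(x)
    i = np.arange(p.n + 1)
    return p.lambdas * (1.0 + (p.q - 1.0) * zpad[i + 3]) * (1.0 + (p.r - 1.0) * zpad[i])


def flow_jacobian(p: EFRBMParams, x: ArrayLike) -> NDArray[np.float64]:
    """Derivatives ``∂g_i/∂x_j`` as an ``(n+1, n)`` matrix.

    ``g_i`` touches at most the four sites ``i-1, i, i+1, i+2``; virtual
    sites contribute no columns.
    """
    x = _as_state(x)
    n = x.size
    if n != p.n:
        raise ValueError(f"state has {n} sites but parameters define n={p.n}")
    X = np.empty(n + 2, dtype=x.dtype)
    X[0] = 1.0
    X[1 : n + 1] = x
    X[n + 1] = 0.0
    zpad = _padded(x)
    D = np.zeros((n + 1, n), dtype=x.dtype)
    for i in range(n + 1):
        occ = X[i]
        exc = 1.0 - X[i + 1]
        A = 1.0 + (p.q - 1.0) * zpad[i + 3]
        B = 1.0 + (p.r - 1.0) * zpad[i]
        lam = p.lambdas[i]
        if 1 <= i <= n:
            D[i, i - 1] += lam * exc * A * B            # ∂/∂x_i
        if 1 <= i + 1 <= n:
            D[i, i] += -lam * occ * A * B               # ∂/∂x_{i+1}
        if 1 <= i + 2 <= n:
            D[i, i + 1] += lam * occ * exc * (p.q - 1.0) * B  # ∂/∂x_{i+2}
        if 1 <= i - 1 <= n:
            D[i, i - 2] += lam * occ * exc * A * (p.r - 1.0)  # ∂/∂x_{i-1}
    return D


def vector_field_jacobian(p: EFRBMParams, x: ArrayLike) -> NDArray[np.float64]:
    """Jacobian of the dynamics, ``J_{ij} = ∂(g_{i-1} - g_i)/∂x_j``."""
    D = flow_jacobian(p, x)
    return D[:-1, :] - D[1:, :]
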