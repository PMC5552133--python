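"""Configuration parsing, serialization and seeded fixture generation.

A run is described by a flat YAML file.  Units: rates are per unit time,
densities dimensionless in [0,1], and the interaction energy ``E`` is
supplied pre-divided by ``K_B T``.  Exactly one of the interaction
representations is given: either the pair ``(r, q)`` or the energy ``E``
(which implies ``q = exp(E/2)``, ``r = exp(-E/2)``).

Example::

    n: 3
    lambdas: [0.5, 0.8, 0.7, 0.6]
    r: 0.5
    q: 2.0
    task: steady-state
    seed: 1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import EFRBMParams, thermo_to_qr

__all__ = [
    "RunConfig",
    "FixtureSpec",
    "ConfigError",
    "load_config",
    "save_config",
    "builtin_params",
    "BUILTIN_EXAMPLES",
    "generate_fixtures",
]

_TASKS = ("simulate", "steady-state", "sweep", "asymptotics", "contraction")


class ConfigError(ValueError):
    """Invalid configuration; ``errors`` lists *every* violated constraint."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass(frozen=True)
class RunConfig:
    """Validated run description: model parameters plus task options."""

    params: EFRBMParams
    task: str = "steady-state"
    seed: int = 0
    options: dict = field(default_factory=dict)
    E: float | None = None  # retained when the energy form was supplied
    output: str | None = None

    def to_dict(self) -> dict:
        d: dict = {
            "n": self.params.n,
            "lambdas": [float(v) for v in self.params.lambdas],
            "task": self.task,
            "seed": self.seed,
        }
        if self.E is not None:
            d["E"] = float(self.E)
        else:
            d["r"] = float(self.params.r)
            d["q"] = float(self.params.q)
        if self.options:
            d["options"] = dict(self.options)
        if self.output is not None:
            d["output"] = self.output
        return d


def _validate(raw: dict) -> RunConfig:
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])

    lambdas = raw.get("lambdas")
    n = raw.get("n")
    if lambdas is None:
        errors.append("missing key: lambdas")
    else:
        try:
            lambdas = [float(v) for v in lambdas]
        except (TypeError, ValueError):
            errors.append("lambdas must be a list of numbers")
            lambdas = None
    if lambdas is not None:
        for i, v in enumerate(lambdas):
            if not v > 0 or not np.isfinite(v):
                errors.append(f"rate λ_{i} must be positive and finite, got {v}")
        if n is not None and len(lambdas) != int(n) + 1:
            errors.append(
                f"n={n} requires {int(n) + 1} rates λ_0..λ_{n}, got {len(lambdas)}"
            )
        elif n is None and len(lambdas) < 2:
            errors.append("at least two rates (λ_0, λ_1) are required")

    has_rq = "r" in raw or "q" in raw
    has_E = "E" in raw
    r = q = E = None
    if has_rq and has_E:
        errors.append("give either the (r, q) pair or the energy E, not both")
    elif has_E:
        try:
            E = float(raw["E"])
            if not np.isfinite(E):
                errors.append(f"E must be finite, got {E}")
        except (TypeError, ValueError):
            errors.append("E must be a number")
    elif has_rq:
        if "r" not in raw:
            errors.append("q given without r")
        if "q" not in raw:
            errors.append("r given without q")
        try:
            r = float(raw.get("r", 1.0))
            q = float(raw.get("q", 1.0))
            if not (r >= 0 and np.isfinite(r)):
                errors.append(f"r must be a nonnegative finite real, got {r}")
            if not (q >= 0 and np.isfinite(q)):
                errors.append(f"q must be a nonnegative finite real, got {q}")
        except (TypeError, ValueError):
            errors.append("r and q must be numbers")
    else:
        errors.append("missing interaction parameters: give (r, q) or E")

    task = raw.get("task", "steady-state")
    if task not in _TASKS:
        errors.append(f"unknown task {task!r}; choose from {_TASKS}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")

    if errors:
        raise ConfigError(errors)

    if E is not None:
        q, r = thermo_to_qr(E)
    params = EFRBMParams(lambdas=np.asarray(lambdas, dtype=float), r=r, q=q)
    return RunConfig(
        params=params,
        task=task,
        seed=seed,
        options=dict(raw.get("options", {})),
        E=E,
        output=raw.get("output"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` enumerating every violated constraint
    (not just the first), or ``FileNotFoundError``.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _validate(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a config canonically (sorted keys, plain YAML) so that
    save→load→save is byte-for-byte idempotent."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True, default_flow_style=False)


#: Reference configurations used throughout the worked examples: the
#: contraction demo (example2), the n=3 convergence demo (example3), the
#: n=2 homogeneous chain (example4), the jam-alleviation chain (example5),
#: the homogeneous jam chain (example6) and the density-separation chain
#: (example8).  Each maps r -> q = 1/r unless q is given explicitly.
BUILTIN_EXAMPLES: dict[str, dict] = {
    "example2": {"lambdas": [1.0, 2.0, 3.0, 4.0], "r": 5.0, "q": 0.2},
    "example3": {"lambdas": [0.5, 0.8, 0.7, 0.6], "r": 0.5, "q": 2.0},
    "example4": {"lambdas": [1.0, 1.0, 1.0], "r": 1.0, "q": 1.0},
    "example5": {"lambdas": [1.0, 1.2, 0.9, 4.0, 0.2, 1.0, 1.1], "r": 1.0, "q": 1.0},
    "example6": {"lambdas": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0], "r": 0.1, "q": 10.0},
    "example8": {"lambdas": [1.0, 1.2, 0.8, 0.95, 1.1, 0.75, 1.15], "r": 1.0, "q": 1.0},
}


def builtin_params(name: str, r: float | None = None) -> EFRBMParams:
    """Named reference configuration, optionally re-coupled at a different
    interaction strength (``q = 1/r``)."""
    if name not in BUILTIN_EXAMPLES:
        raise KeyError(f"unknown builtin {name!r}; choose from {sorted(BUILTIN_EXAMPLES)}")
    spec = BUILTIN_EXAMPLES[name]
    if r is not None:
        return EFRBMParams.coupled(spec["lambdas"], r)
    return EFRBMParams(
        lambdas=np.asarray(spec["lambdas"], dtype=float), r=spec["r"], q=spec["q"]
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for seeded random parameter sets: lattice sizes uniform on
    ``n_range``, rates log-uniform on ``lam_range``, ``r`` log-uniform on
    ``r_range`` with ``q = 1/r`` when ``couple_q`` (else q drawn like r).
    Generated sets always satisfy the model invariants with ``q, r > 0``."""

    n_range: tuple[int, int] = (2, 6)
    lam_range: tuple[float, float] = (0.1, 10.0)
    r_range: tuple[float, float] = (0.1, 10.0)
    couple_q: bool = True
    count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        errs = []
        if self.n_range[0] < 1 or self.n_range[1] < self.n_range[0]:
            errs.append(f"empty lattice-size range {self.n_range}")
        for nm, (lo, hi) in (("lam_range", self.lam_range), ("r_range", self.r_range)):
            if not (0 < lo <= hi):
                errs.append(f"empty or non-positive {nm} {(lo, hi)}")
        if self.count < 1:
            errs.append(f"count must be >= 1, got {self.count}")
        if errs:
            raise ConfigError(errs)


def generate_fixtures(spec: FixtureSpec) -> list[EFRBMParams]:
    """Reproducible random parameter sets (same seed, same list)."""
    rng = np.random.default_rng(spec.seed)
    out: list[EFRBMParams] = []
    log_lam = np.log(spec.lam_range)
    log_r = np.log(spec.r_range)
    for _ in range(spec.count):
        n = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
        lam = np.exp(rng.uniform(log_lam[0], log_lam[1], size=n + 1))
        r = float(np.exp(rng.uniform(log_r[0], log_r[1])))
        q = 1.0 / r if spec.couple_q else float(np.exp(rng.uniform(log_r[0], log_r[1])))
        out.append(EFRBMParams(lambdas=lam, r=r, q=q))
    return out
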