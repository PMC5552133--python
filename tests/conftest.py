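import numpy as np
import pytest

from efrbm import EFRBMParams, builtin_params


@pytest.fixture
def ex2_params() -> EFRBMParams:
    """n=3 contraction demo: λ=[1,2,3,4], r=5, q=1/5."""
    return builtin_params("example2")


@pytest.fixture
def ex3_params() -> EFRBMParams:
    """n=3 convergence demo rates with r=1/2, q=2."""
    return builtin_params("example3")


@pytest.fixture
def ex5_params() -> EFRBMParams:
    """n=6 jam-alleviation chain at the RFM point (r=q=1)."""
    return builtin_params("example5")


@pytest.fixture
def ex8_lambdas() -> np.ndarray:
    return np.array([1.0, 1.2, 0.8, 0.95, 1.1, 0.75, 1.15])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250925)


def random_params(rng: np.random.Generator, n: int, r_lo: float = 0.2,
                  r_hi: float = 5.0) -> EFRBMParams:
    """Random coupled (q = 1/r) parameter set with log-uniform rates."""
    lam = np.exp(rng.uniform(np.log(0.2), np.log(5.0), size=n + 1))
    r = float(np.exp(rng.uniform(np.log(r_lo), np.log(r_hi))))
    return EFRBMParams.coupled(lam, r)
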