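import numpy as np
import pytest

from p62agg import ContinuumState, RateConstants


def unit_params(kappa_m: float, n: int = 5) -> RateConstants:
    """The canonical parameter family: all binding/unbinding constants 1,
    varying only the cross-link breaking rate."""
    return RateConstants(n=n, kappa1=1.0, kappa2=1.0, kappa3=1.0,
                         kappa_m1=1.0, kappa_m=kappa_m)


@pytest.fixture
def params_finite():
    """Finite-size regime (0 < alpha_bar < 1)."""
    return unit_params(0.6)


@pytest.fixture
def params_extinction():
    """Extinction regime (alpha_bar slightly above 1)."""
    return unit_params(0.93)


@pytest.fixture
def params_growth():
    """Unbounded-growth regime (alpha_bar < 0)."""
    return unit_params(0.2)


@pytest.fixture
def params_no_breaking():
    """No cross-link breaking (kappa_m = 0): linear growth."""
    return unit_params(0.0)


@pytest.fixture
def init_state():
    """Reference initial aggregate used by the regime simulations."""
    return ContinuumState(2.0, 4.0, 3.0)


def random_rates(rng: np.random.Generator, n_choices=(3, 4, 5, 8)) -> RateConstants:
    """Log-uniform rate constants in [0.05, 5] with a random oligomer size."""
    k = np.exp(rng.uniform(np.log(0.05), np.log(5.0), size=5))
    return RateConstants(n=int(rng.choice(n_choices)), kappa1=float(k[0]),
                         kappa2=float(k[1]), kappa3=float(k[2]),
                         kappa_m1=float(k[3]), kappa_m=float(k[4]))
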