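"""Reference parameter sets spanning the three dynamical regimes.

The four named sets share ``kappa1 = kappa2 = kappa3 = kappa_m1 = 1`` and
``n = 5`` with initial continuum state ``(2, 4, 3)`` and differ only in the
cross-link breaking rate: ``kappa_m = 0.6`` (finite size), ``0.93``
(extinction), ``0.2`` (unbounded growth) and ``0`` (breaking-free linear
growth).  Each fixture carries the analytic expectations that apply to its
regime — ``alpha_bar``, the closed-form steady state, the quadratic-growth
coefficients, or the breaking-free limits — regenerated from the closed
forms on every call, so they are bit-identical across runs.

``generate_fixtures`` also emits seeded random admissible discrete states for
exercising the stochastic layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .discrete import DiscreteAggregate, is_admissible
from .model_core import ContinuumState
from .params import RateConstants
from .regimes import (
    alpha_bar,
    asymptotic_coefficients,
    classify_regime,
    kappa_zero_limits,
    steady_state,
)

__all__ = ["Fixture", "FixtureSet", "regime_fixtures", "random_discrete_states",
           "generate_fixtures"]

_INIT = ContinuumState(2.0, 4.0, 3.0)


@dataclass(frozen=True)
class Fixture:
    name: str
    params: RateConstants
    init: ContinuumState
    expected: dict = field(hash=False)

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "params": self.params.as_dict(),
            "init": {"p": self.init.p, "q": self.init.q, "r": self.init.r},
            "expected": self.expected,
        }


@dataclass(frozen=True)
class FixtureSet:
    fixtures: tuple[Fixture, ...]
    discrete_states: tuple[DiscreteAggregate, ...]

    def __getitem__(self, name: str) -> Fixture:
        for fx in self.fixtures:
            if fx.name == name:
                return fx
        raise KeyError(name)


def _fixture(name: str, kappa_m: float) -> Fixture:
    params = RateConstants(n=5, kappa1=1.0, kappa2=1.0, kappa3=1.0,
                           kappa_m1=1.0, kappa_m=kappa_m)
    expected: dict = {}
    if kappa_m == 0.0:
        lim = kappa_zero_limits(params)
        expected["kappa_zero"] = {
            "p_inf": lim.p_inf, "s_inf": lim.s_inf,
            "slope_q": lim.slope_q, "slope_r": lim.slope_r,
        }
    else:
        ab = alpha_bar(params)
        expected["alpha_bar"] = ab
        expected["regime"] = classify_regime(params).regime.value
        ss = steady_state(params)
        if ss is not None:
            expected["steady_state"] = {"p": ss.p, "q": ss.q, "r": ss.r}
        if ab < 0:
            co = asymptotic_coefficients(params)
            expected["asymptotics"] = {
                "p1": co.p1, "q2": co.q2, "r2": co.r2, "s1": co.s1,
            }
    return Fixture(name=name, params=params, init=_INIT, expected=expected)


def regime_fixtures() -> FixtureSet:
    """The four named parameter sets with their analytic expectations,
    plus 10 seeded random admissible discrete states."""
    fixtures = (
        _fixture("fig3_left", 0.6),     # finite size
        _fixture("fig3_right", 0.93),   # extinction
        _fixture("fig4", 0.2),          # unbounded growth
        _fixture("kappa_zero", 0.0),    # linear growth, no breaking
    )
    return FixtureSet(fixtures=fixtures,
                      discrete_states=random_discrete_states(10, n=5, seed=20210))


def random_discrete_states(
    count: int, n: int, seed: int, k_max: int = 12
) -> tuple[DiscreteAggregate, ...]:
    """Seeded random admissible discrete states (rejection sampling)."""
    rng = np.random.default_rng(seed)
    states = []
    while len(states) < count:
        k = int(rng.integers(2, k_max + 1))
        j = int(rng.integers(k - 1, n * k // 2 + 1))
        i = int(rng.integers(0, n * k - 2 * j + 1))
        if is_admissible(i, j, k, n):
            states.append(DiscreteAggregate(i, j, k))
    return tuple(states)


def generate_fixtures(out_dir) -> FixtureSet:
    """Write the fixture set to ``out_dir`` as JSON, one file per fixture
    plus ``discrete_states.json``; returns the in-memory set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fxset = regime_fixtures()
    for fx in fxset.fixtures:
        with open(out / f"{fx.name}.json", "w", encoding="utf-8") as fh:
            json.dump(fx.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    with open(out / "discrete_states.json", "w", encoding="utf-8") as fh:
        json.dump([s.as_tuple() for s in fxset.discrete_states], fh)
        fh.write("\n")
    return fxset
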