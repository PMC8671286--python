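"""Discrete reaction scheme and exact stochastic simulation.

An aggregate is a triplet ``(i, j, k)``: one-hand bound cross-linkers,
both-hand bound cross-linkers, and p62 oligomers of size ``n``.  A triplet is
*admissible* when ``k >= 2`` (it takes two oligomers to make an aggregate),
``j >= k - 1`` (enough cross-links to be connected) and ``i + 2j <= n k``
(binding sites are finite).

Six reactions act on the triplet, all mass action:

====  =========================================  ==============================
 id    transition                                 propensity
====  =========================================  ==============================
 1     Ubi binds one hand: ``(i+1, j, k)``        ``kappa1 * (nk - i - 2j)``
 2     free oligomer joins: ``(i-1, j+1, k+1)``   ``kappa2 * i``
 3     compactification: ``(i-1, j+1, k)``        ``kappa3' * i * (nk - i - 2j)``
 -1    one-hand Ubi falls off: ``(i-1, j, k)``    ``kappa_m1 * i``
 -2    oligomer detaches:                         ``kappa_m * alpha_{j,k} * j``
       ``(i+1-l, j-1, k-1)``
 -3    loosening: ``(i+1, j-1, k)``               ``kappa_m * (1-alpha_{j,k}) * j``
====  =========================================  ==============================

Reactions -2 and -3 are the two outcomes of the same event — a cross-link
breaking at total rate ``kappa_m * j`` — split by the probability
``alpha_{j,k}`` that the broken link was the detaching oligomer's only
connection.  On detachment the oligomer carries ``l`` one-hand bound
cross-linkers with it, with ``l`` the rounded expected share of ``i``.

Here ``kappa3`` in :class:`~p62agg.params.RateConstants` is read as the
second-order constant kappa3' (see :mod:`p62agg.params` for the conversion to
the continuum level).

Sample paths are generated with the direct (first-reaction-time) stochastic
simulation algorithm: exponential waiting times from the total propensity and
a single uniform draw to pick the reaction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import AdmissibilityError, DomainError
from .params import RateConstants

__all__ = [
    "DiscreteAggregate",
    "PropensityVector",
    "DiscreteTrajectory",
    "Termination",
    "AGGREGATE_LOST",
    "REACTIONS",
    "is_admissible",
    "alpha_discrete",
    "ell_choice",
    "propensities",
    "apply_reaction",
    "ssa_run",
    "ssa_ensemble",
    "sample_on_grid",
    "enumerate_admissible",
]

#: reaction identifiers in propensity order
REACTIONS: tuple[int, ...] = (1, 2, 3, -1, -2, -3)


class _AggregateLost:
    """Sentinel returned by :func:`apply_reaction` when the aggregate
    dissolves (oligomer loss at ``k = 2``)."""

    def __repr__(self) -> str:  # pragma: no cover
        return "AGGREGATE_LOST"


AGGREGATE_LOST = _AggregateLost()


class Termination(str, enum.Enum):
    REACHED_T_MAX = "reached_t_max"
    AGGREGATE_LOST = "aggregate_lost"
    ABSORBING_STATE = "absorbing_state"


@dataclass(frozen=True)
class DiscreteAggregate:
    """Admissibility is not checked at construction (``n`` is not stored);
    use :func:`is_admissible` or pass through the validating operations."""

    i: int
    j: int
    k: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.i, self.j, self.k)


@dataclass(frozen=True)
class PropensityVector:
    r1: float
    r2: float
    r3: float
    r_m1: float
    r_m2: float
    r_m3: float

    def as_array(self) -> np.ndarray:
        """Rates in :data:`REACTIONS` order."""
        return np.array([self.r1, self.r2, self.r3, self.r_m1, self.r_m2, self.r_m3])

    @property
    def total(self) -> float:
        return self.r1 + self.r2 + self.r3 + self.r_m1 + self.r_m2 + self.r_m3


@dataclass
class DiscreteTrajectory:
    """Event-resolved sample path: state ``states[m]`` holds on
    ``[times[m], times[m+1])``; ``reactions[m]`` produced ``states[m]`` (0 for
    the initial state)."""

    times: np.ndarray
    states: np.ndarray  # shape (events+1, 3), columns i, j, k
    reactions: np.ndarray  # int codes, 0 for the initial entry
    termination: Termination
    t_max: float

    def __len__(self) -> int:
        return len(self.times)

    def write_csv(self, path) -> None:
        """Event log ``t,reaction,i,j,k`` (initial state has reaction 0)."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("t,reaction,i,j,k\n")
            for m in range(len(self.times)):
                i, j, k = self.states[m]
                fh.write(f"{self.times[m]!r},{self.reactions[m]},{i},{j},{k}\n")


def is_admissible(i: int, j: int, k: int, n: int) -> bool:
    """``k >= 2``, ``j >= k - 1`` and ``i + 2j <= n k``, with all counts
    nonnegative."""
    return i >= 0 and j >= 0 and k >= 2 and j >= k - 1 and i + 2 * j <= n * k


def _check_admissible(state: DiscreteAggregate, n: int) -> None:
    if not is_admissible(state.i, state.j, state.k, n):
        raise AdmissibilityError(f"state {state.as_tuple()} is inadmissible for n={n}")


def alpha_discrete(j: int, k: int, n: int) -> float:
    """Probability that a breaking cross-link detaches an oligomer:
    ``(nk - 2j - n + 2)_+ / ((n-2)k + 4 - n)``.

    As a function of ``j`` this interpolates linearly between 1 on a chain
    (``j = k - 1``) and 0 on a tightly connected aggregate
    (``nk - 2j <= n - 2``).
    """
    num = n * k - 2 * j - n + 2
    if num <= 0:
        return 0.0
    return num / ((n - 2) * k + 4 - n)


def ell_choice(i: int, j: int, k: int, n: int) -> int:
    """Number of one-hand bound cross-linkers leaving with a detaching
    oligomer: the closest integer to ``(n-1) i / (nk - 2j)`` (ties half-up).

    Defined exactly when detachment is possible, ``nk - 2j >= n - 1``; the
    result always satisfies
    ``(n - 1 - nk + i + 2j)_+ <= l <= min(i, n-1)``, so the post-detachment
    state is admissible.
    """
    denom = n * k - 2 * j
    if denom < n - 1:
        raise DomainError(
            f"ell_choice requires nk - 2j >= n - 1 (detachment possible), "
            f"got nk - 2j = {denom} for (i, j, k) = {(i, j, k)}, n = {n}"
        )
    # floor(a/b + 1/2) on integers: (2a + b) // (2b)
    return (2 * (n - 1) * i + denom) // (2 * denom)


def propensities(state: DiscreteAggregate, params: RateConstants) -> PropensityVector:
    """Mass-action propensities at ``state``; rates whose enabling condition
    fails are exactly zero (every rate carries the corresponding count
    factor)."""
    _check_admissible(state, params.n)
    i, j, k = state.i, state.j, state.k
    n = params.n
    free = n * k - i - 2 * j
    alpha = alpha_discrete(j, k, n)
    return PropensityVector(
        r1=params.kappa1 * free,
        r2=params.kappa2 * i,
        r3=params.kappa3 * i * free,
        r_m1=params.kappa_m1 * i,
        r_m2=params.kappa_m * alpha * j,
        r_m3=params.kappa_m * (1.0 - alpha) * j,
    )


def _enabled(state: DiscreteAggregate, reaction: int, n: int) -> bool:
    i, j, k = state.i, state.j, state.k
    free = n * k - i - 2 * j
    if reaction == 1:
        return free >= 1
    if reaction == 2:
        return i >= 1
    if reaction == 3:
        return i >= 1 and free >= 1
    if reaction == -1:
        return i >= 1
    if reaction == -2:
        # detachment possible exactly when alpha_{j,k} > 0
        return j >= 1 and n * k - 2 * j >= n - 1
    if reaction == -3:
        return j >= k  # 1 - alpha > 0 requires an excess cross-link
    raise DomainError(f"unknown reaction {reaction!r}")


def apply_reaction(state: DiscreteAggregate, reaction: int, n: int):
    """Apply one reaction's stoichiometry; returns the new admissible state,
    or :data:`AGGREGATE_LOST` when an oligomer detaches at ``k = 2``."""
    _check_admissible(state, n)
    if not _enabled(state, reaction, n):
        raise DomainError(
            f"reaction {reaction} is not enabled at state {state.as_tuple()}"
        )
    i, j, k = state.i, state.j, state.k
    if reaction == 1:
        new = DiscreteAggregate(i + 1, j, k)
    elif reaction == 2:
        new = DiscreteAggregate(i - 1, j + 1, k + 1)
    elif reaction == 3:
        new = DiscreteAggregate(i - 1, j + 1, k)
    elif reaction == -1:
        new = DiscreteAggregate(i - 1, j, k)
    elif reaction == -2:
        if k == 2:
            return AGGREGATE_LOST
        ell = ell_choice(i, j, k, n)
        new = DiscreteAggregate(i + 1 - ell, j - 1, k - 1)
    else:  # -3
        new = DiscreteAggregate(i + 1, j - 1, k)
    _check_admissible(new, n)
    return new


def ssa_run(
    init: DiscreteAggregate,
    params: RateConstants,
    t_max: float,
    seed: int | np.random.Generator,
    *,
    max_events: Optional[int] = None,
) -> DiscreteTrajectory:
    """Direct-method stochastic simulation of the reaction scheme.

    Produces a statistically exact sample path of the continuous-time Markov
    chain, reproducible for a given ``seed`` (an int or an existing
    ``numpy.random.Generator``).  Terminates at ``t_max``, when the aggregate
    is lost (oligomer detachment at ``k = 2``), or in an absorbing state.
    """
    _check_admissible(init, params.n)
    if not t_max > 0:
        raise DomainError(f"t_max must be positive, got {t_max!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = params.n
    k1, k2, k3p = params.kappa1, params.kappa2, params.kappa3
    km1, km = params.kappa_m1, params.kappa_m

    i, j, k = init.i, init.j, init.k
    t = 0.0
    times = [0.0]
    states = [(i, j, k)]
    codes = [0]
    termination = Termination.REACHED_T_MAX

    events = 0
    while True:
        if max_events is not None and events >= max_events:
            break
        free = n * k - i - 2 * j
        num = n * k - 2 * j - n + 2
        alpha = num / ((n - 2) * k + 4 - n) if num > 0 else 0.0
        a1 = k1 * free
        a2 = k2 * i
        a3 = k3p * i * free
        a4 = km1 * i
        a5 = km * alpha * j
        a6 = km * (1.0 - alpha) * j
        total = a1 + a2 + a3 + a4 + a5 + a6
        if total <= 0.0:
            termination = Termination.ABSORBING_STATE
            break
        t_next = t + rng.exponential(1.0 / total)
        if t_next > t_max:
            break
        t = t_next
        u = rng.random() * total
        if u < a1:
            i += 1
            code = 1
        elif u < a1 + a2:
            i -= 1
            j += 1
            k += 1
            code = 2
        elif u < a1 + a2 + a3:
            i -= 1
            j += 1
            code = 3
        elif u < a1 + a2 + a3 + a4:
            i -= 1
            code = -1
        elif u < a1 + a2 + a3 + a4 + a5:
            code = -2
            if k == 2:
                times.append(t)
                states.append((i, j, k))  # pre-loss state recorded at loss time
                codes.append(code)
                termination = Termination.AGGREGATE_LOST
                break
            denom = n * k - 2 * j
            ell = (2 * (n - 1) * i + denom) // (2 * denom)
            i += 1 - ell
            j -= 1
            k -= 1
        else:
            i += 1
            j -= 1
            code = -3
        times.append(t)
        states.append((i, j, k))
        codes.append(code)
        events += 1
        if termination is Termination.AGGREGATE_LOST:  # pragma: no cover
            break

    return DiscreteTrajectory(
        times=np.asarray(times, dtype=float),
        states=np.asarray(states, dtype=np.int64),
        reactions=np.asarray(codes, dtype=np.int64),
        termination=termination,
        t_max=float(t_max),
    )


def sample_on_grid(traj: DiscreteTrajectory, grid: Sequence[float]) -> np.ndarray:
    """State at each grid time, by last event at or before ``t``.

    Grid times beyond the trajectory's end (loss/absorption) repeat the final
    recorded state.  Returns an array of shape ``(len(grid), 3)``.
    """
    grid = np.asarray(grid, dtype=float)
    idx = np.searchsorted(traj.times, grid, side="right") - 1
    idx = np.clip(idx, 0, len(traj.times) - 1)
    return traj.states[idx]


def ssa_ensemble(
    init: DiscreteAggregate,
    params: RateConstants,
    t_max: float,
    grid: Sequence[float],
    replicates: int,
    seed: int,
    k0: float,
) -> dict[str, np.ndarray]:
    """Ensemble of SSA runs, summarized as scaled means and standard errors.

    States are scaled by ``k0`` (``p = i/k0`` etc.) so the means are directly
    comparable with the continuum solution.  Returns a dict with keys ``t``,
    ``mean_p/q/r`` and ``se_p/q/r``.  Lost aggregates contribute their final
    pre-loss state from the loss time onward.
    """
    if replicates < 2:
        raise DomainError("ssa_ensemble needs at least 2 replicates")
    grid = np.asarray(grid, dtype=float)
    streams = np.random.SeedSequence(seed).spawn(replicates)
    samples = np.empty((replicates, len(grid), 3), dtype=float)
    for m, ss in enumerate(streams):
        traj = ssa_run(init, params, t_max, np.random.default_rng(ss))
        samples[m] = sample_on_grid(traj, grid) / k0
    mean = samples.mean(axis=0)
    se = samples.std(axis=0, ddof=1) / np.sqrt(replicates)
    return {
        "t": grid,
        "mean_p": mean[:, 0], "mean_q": mean[:, 1], "mean_r": mean[:, 2],
        "se_p": se[:, 0], "se_q": se[:, 1], "se_r": se[:, 2],
    }


def enumerate_admissible(n: int, k_max: int, i_max: Optional[int] = None) -> Iterator[DiscreteAggregate]:
    """All admissible states with ``k <= k_max`` (and optionally ``i <= i_max``).

    Useful for brute-force verification of propensity and detachment rules on
    small state spaces.
    """
    for k in range(2, k_max + 1):
        for j in range(k - 1, n * k // 2 + 1):
            top = n * k - 2 * j
            if i_max is not None:
                top = min(top, i_max)
            for i in range(0, top + 1):
                yield DiscreteAggregate(i, j, k)
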