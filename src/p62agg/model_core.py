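"""Continuum description of a p62-ubiquitin aggregate.

The aggregate is described by three scaled, nonnegative quantities

* ``p`` — one-hand bound cross-linkers,
* ``q`` — both-hand bound cross-linkers (the cross-links proper),
* ``r`` — p62 oligomers,

evolving under mass-action kinetics:

.. math::

    \\dot p &= (\\kappa_1 - \\kappa_3 p)(nr - p - 2q)
              + \\kappa_- q\\Bigl(1 - \\frac{(n-1)p}{(n-2)r}\\Bigr)
              - (\\kappa_2 + \\kappa_{-1}) p, \\\\
    \\dot q &= \\kappa_2 p + \\kappa_3 p (nr - p - 2q) - \\kappa_- q, \\\\
    \\dot r &= \\kappa_2 p - \\kappa_- q\\, \\alpha(q, r),

with :math:`\\alpha(q,r) = (nr - 2q)/((n-2)r)` the probability that a breaking
cross-link detaches an oligomer (one for a chain, zero for a fully packed
aggregate).

A state is *admissible* when the number of free binding sites
``s = n r - p - 2q`` is nonnegative and the aggregate holds enough
cross-links to be connected, ``q >= r``.  Both conditions are propagated by
the flow; the integrator only repairs round-off sized violations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import AdmissibilityError, DomainError, NumericsError
from .params import RateConstants

__all__ = [
    "ContinuumState",
    "Trajectory",
    "alpha_continuum",
    "rhs",
    "auxiliary_quantities",
    "check_admissible",
    "project_to_admissible",
    "integrate",
]

#: absolute slack allowed on the constraint surface before an input is rejected
_CONSTRUCTION_TOL = 1e-9
#: violations smaller than this (relative to state magnitude) are clipped,
#: larger ones are treated as integrator failure
_CLIP_TOL = 1e-10


@dataclass(frozen=True)
class ContinuumState:
    """An admissible continuum aggregate state ``(p, q, r)``.

    Construction validates nonnegativity and the n-free part of
    admissibility (``q >= r``); the free-site constraint needs ``n`` and is
    checked by :func:`check_admissible`.
    """

    p: float
    q: float
    r: float

    def __post_init__(self) -> None:
        scale = max(1.0, abs(self.p), abs(self.q), abs(self.r))
        tol = _CONSTRUCTION_TOL * scale
        for name in ("p", "q", "r"):
            if not getattr(self, name) >= -tol:
                raise AdmissibilityError(
                    f"{name} must be nonnegative, got {getattr(self, name)!r}"
                )
        if self.q < self.r - tol:
            raise AdmissibilityError(
                f"connectivity requires q >= r, got q={self.q!r}, r={self.r!r}"
            )

    def s(self, n: int) -> float:
        """Free binding sites ``n r - p - 2 q``."""
        return n * self.r - self.p - 2.0 * self.q

    @property
    def gap(self) -> float:
        """Excess cross-links ``q - r`` above the connectivity minimum."""
        return self.q - self.r

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p, self.q, self.r)


def check_admissible(state: ContinuumState, n: int, tol: float = _CONSTRUCTION_TOL) -> None:
    """Raise :class:`AdmissibilityError` unless ``state`` is admissible for ``n``."""
    scale = max(1.0, state.p, state.q, state.r)
    if state.s(n) < -tol * scale:
        raise AdmissibilityError(
            f"free-site constraint violated: s = {state.s(n)!r} < 0 "
            f"for state {state.as_tuple()} with n={n}"
        )
    if state.gap < -tol * scale:
        raise AdmissibilityError(
            f"connectivity constraint violated: q - r = {state.gap!r} < 0"
        )


def alpha_continuum(q: float, r: float, n: int) -> float:
    """Oligomer-detachment probability ``alpha(q, r) = (nr - 2q)/((n-2)r)``.

    Equals 1 on a chain (``q = r``) and 0 on a fully packed aggregate
    (``2q = nr``); lies in [0, 1] for every admissible state.
    """
    if not r > 0:
        raise DomainError(f"alpha(q, r) requires r > 0, got r={r!r}")
    tol = _CONSTRUCTION_TOL * max(1.0, q, r)
    if q < r - tol or 2.0 * q > n * r + tol:
        raise DomainError(
            f"(q, r) = ({q!r}, {r!r}) is not part of an admissible state for n={n}"
        )
    value = (n * r - 2.0 * q) / ((n - 2) * r)
    return min(1.0, max(0.0, value))


def auxiliary_quantities(state: ContinuumState, n: int) -> tuple[float, float]:
    """Return ``(s, gap) = (nr - p - 2q, q - r)`` — both nonnegative for
    admissible states."""
    check_admissible(state, n)
    return state.s(n), state.gap


def _rhs_raw(p: float, q: float, r: float, c: RateConstants) -> tuple[float, float, float]:
    """Right-hand side without validation; continuous extension by 0 at the
    origin (all terms carry a factor p, q or s <= nr)."""
    n = c.n
    if r <= 0.0:
        return (0.0, 0.0, 0.0)
    s = n * r - p - 2.0 * q
    alpha = (n * r - 2.0 * q) / ((n - 2) * r)
    dp = (
        (c.kappa1 - c.kappa3 * p) * s
        + c.kappa_m * q * (1.0 - (n - 1) * p / ((n - 2) * r))
        - (c.kappa2 + c.kappa_m1) * p
    )
    dq = c.kappa2 * p + c.kappa3 * p * s - c.kappa_m * q
    dr = c.kappa2 * p - c.kappa_m * q * alpha
    return (dp, dq, dr)


def rhs(state: ContinuumState, params: RateConstants) -> tuple[float, float, float]:
    """Mass-action right-hand side ``(dp/dt, dq/dt, dr/dt)`` at ``state``.

    The vector field is undefined at ``r = 0`` but extends continuously by
    zero on admissible states; exactly the origin is accepted and mapped to
    the zero rate.
    """
    if state.r <= 0.0:
        if state.p > _CONSTRUCTION_TOL or state.q > _CONSTRUCTION_TOL:
            raise DomainError(
                f"state {state.as_tuple()} with r = 0 but (p, q) != (0, 0) "
                "is inadmissible"
            )
        return (0.0, 0.0, 0.0)
    check_admissible(state, params.n)
    return _rhs_raw(state.p, state.q, state.r, params)


def project_to_admissible(p: float, q: float, r: float, n: int) -> tuple[float, float, float]:
    """Clip round-off sized constraint violations onto the admissible set.

    Used only by the integrator's post-step repair; violations larger than
    round-off are a hard error upstream.
    """
    p, q, r = max(p, 0.0), max(q, 0.0), max(r, 0.0)
    if q < r:
        q = r
    s = n * r - p - 2.0 * q
    if s < 0.0:
        # shrink p first (it enters s linearly), then q toward the surface
        p = max(0.0, p + s)
        s = n * r - p - 2.0 * q
        if s < 0.0:
            q = max(r, q + s / 2.0)
    return p, q, r


@dataclass
class Trajectory:
    """A computed continuum trajectory on an output grid.

    ``terminated_at_origin`` is the time at which the extinction stop fired
    (aggregate dissolved), or ``None`` if the run reached ``t_end``.
    """

    times: np.ndarray
    p: np.ndarray
    q: np.ndarray
    r: np.ndarray
    n: int
    terminated_at_origin: Optional[float] = None
    params: Optional[RateConstants] = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def s(self) -> np.ndarray:
        return self.n * self.r - self.p - 2.0 * self.q

    @property
    def gap(self) -> np.ndarray:
        return self.q - self.r

    def state(self, index: int) -> ContinuumState:
        return ContinuumState(float(self.p[index]), float(self.q[index]), float(self.r[index]))

    @property
    def final_state(self) -> ContinuumState:
        return self.state(-1)

    def write_csv(self, path) -> None:
        """Write ``t,p,q,r,s,gap`` at full (repr round-trip) precision."""
        s, gap = self.s, self.gap
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("t,p,q,r,s,gap\n")
            for i in range(len(self.times)):
                fh.write(
                    f"{float(self.times[i])!r},{float(self.p[i])!r},"
                    f"{float(self.q[i])!r},{float(self.r[i])!r},"
                    f"{float(s[i])!r},{float(gap[i])!r}\n"
                )


def integrate(
    params: RateConstants,
    init: ContinuumState,
    t_end: float,
    output_grid: Optional[Sequence[float]] = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    eps_origin: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the continuum system from ``init`` up to ``t_end``.

    Parameters
    ----------
    output_grid:
        Times at which the solution is reported; defaults to 201 evenly
        spaced points on ``[0, t_end]``.  Must start at 0 and be strictly
        increasing.
    eps_origin:
        Extinction radius: once ``r`` drops below this value (which, by
        admissibility, forces ``p`` and ``q`` down with it) the aggregate is
        considered dissolved and integration stops with
        ``terminated_at_origin`` set.

    The returned trajectory satisfies, up to integration tolerance, the a
    priori bounds ``p+q+r <= (p0+q0+r0) exp(t max(n kappa1, kappa2))`` and
    ``r >= 2q/n >= (2 q0/n) exp(-kappa_m t)``.
    """
    if not t_end > 0:
        raise DomainError(f"t_end must be positive, got {t_end!r}")
    if not init.r > 0:
        raise DomainError("initial state must have r > 0")
    check_admissible(init, params.n)

    if output_grid is None:
        grid = np.linspace(0.0, t_end, 201)
    else:
        grid = np.asarray(output_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise DomainError("output_grid must be strictly increasing")
        if not math.isclose(grid[0], 0.0, abs_tol=1e-15) or grid[-1] > t_end * (1 + 1e-12):
            raise DomainError("output_grid must start at 0 and end at or before t_end")

    c = params

    def f(_t, y):
        return _rhs_raw(y[0], y[1], y[2], c)

    def extinct(_t, y):
        return y[2] - eps_origin

    extinct.terminal = True
    extinct.direction = -1.0

    sol = solve_ivp(
        f,
        (0.0, float(t_end)),
        np.array(init.as_tuple(), dtype=float),
        method=method,
        t_eval=grid,
        rtol=rtol,
        atol=atol,
        events=extinct,
        dense_output=False,
    )
    if sol.status == -1:
        last = None
        if sol.y.shape[1] > 0:
            pp, qq, rr = project_to_admissible(
                sol.y[0, -1], sol.y[1, -1], sol.y[2, -1], c.n
            )
            last = ContinuumState(pp, qq, rr)
        raise NumericsError(
            f"integration failed: {sol.message}",
            last_state=last,
            last_time=float(sol.t[-1]) if len(sol.t) else None,
        )

    times = sol.t
    P, Q, R = sol.y[0].copy(), sol.y[1].copy(), sol.y[2].copy()

    terminated_at = None
    if sol.status == 1 and sol.t_events[0].size:
        terminated_at = float(sol.t_events[0][0])
        # append the event state so the trajectory visibly ends at the stop
        ev = sol.y_events[0][0]
        if len(times) == 0 or terminated_at > times[-1]:
            times = np.append(times, terminated_at)
            P, Q, R = np.append(P, ev[0]), np.append(Q, ev[1]), np.append(R, ev[2])

    # repair round-off sized constraint violations; larger ones are a bug
    scale = np.maximum(1.0, np.maximum(P, np.maximum(Q, R)))
    s = c.n * R - P - 2.0 * Q
    worst = max(
        float(np.max(-np.minimum(P, 0.0) / scale, initial=0.0)),
        float(np.max(-np.minimum(Q, 0.0) / scale, initial=0.0)),
        float(np.max(-np.minimum(R, 0.0) / scale, initial=0.0)),
        float(np.max(-np.minimum(s, 0.0) / scale, initial=0.0)),
        float(np.max(-np.minimum(Q - R, 0.0) / scale, initial=0.0)),
    )
    if worst > max(_CLIP_TOL, 100.0 * rtol):
        raise NumericsError(
            f"integrator left the admissible set by {worst:.3e} (relative); "
            "tighten tolerances"
        )
    for idx in range(len(times)):
        P[idx], Q[idx], R[idx] = project_to_admissible(P[idx], Q[idx], R[idx], c.n)

    return Trajectory(
        times=times, p=P, q=Q, r=R, n=c.n,
        terminated_at_origin=terminated_at, params=params,
    )
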