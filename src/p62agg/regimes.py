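"""Long-time behaviour: steady states, regimes, and growth asymptotics.

The fate of an aggregate is governed by a single closed-form parameter

.. math::

    \\bar\\alpha = \\frac{n}{n-2}
      + \\frac{\\kappa_{-1} + \\kappa_1
        - \\sqrt{(\\kappa_1+\\kappa_{-1})^2 + 4\\kappa_1\\kappa_2(n-1)}}
             {\\kappa_-(n-1)} .

* ``alpha_bar >= 1`` — the aggregate dissolves (extinction),
* ``0 < alpha_bar < 1`` — the size saturates at an explicitly computable
  steady state,
* ``alpha_bar <= 0`` — unbounded growth, quadratic in time for the
  cross-link and oligomer counts, linear for the one-hand bound count.

For ``kappa_m = 0`` (no cross-link breaking) the dynamics reduce to a planar
system in ``(p, s)`` with a globally attracting equilibrium and linear growth
of ``q`` and ``r``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DomainError
from .model_core import ContinuumState, Trajectory
from .params import RateConstants

__all__ = [
    "Regime",
    "RegimeReport",
    "AsymptoticCoefficients",
    "KappaZeroLimits",
    "alpha_bar",
    "q_hat",
    "classify_regime",
    "steady_state",
    "critical_kappa_minus",
    "asymptotic_coefficients",
    "kappa_zero_limits",
    "lyapunov_value",
    "exponent_estimate",
]

#: relative tolerance below which alpha_bar counts as sitting on a regime boundary
BOUNDARY_TOL = 1e-9


class Regime(str, enum.Enum):
    EXTINCTION = "extinction"
    FINITE_SIZE = "finite_size"
    UNBOUNDED_GROWTH = "unbounded_growth"


def _require_positive_rates(params: RateConstants, *, need_kappa_m: bool = True) -> None:
    names = ["kappa1", "kappa2", "kappa3", "kappa_m1"]
    if need_kappa_m:
        names.append("kappa_m")
    for name in names:
        if not getattr(params, name) > 0:
            if name == "kappa_m":
                raise DomainError(
                    "alpha_bar is undefined for kappa_m = 0; "
                    "use kappa_zero_limits for the breaking-free dynamics"
                )
            raise DomainError(f"{name} must be > 0, got {getattr(params, name)!r}")


def alpha_bar(params: RateConstants) -> float:
    """Regime parameter: detachment probability at the candidate steady state."""
    _require_positive_rates(params)
    n = params.n
    k1, k2, km1, km = params.kappa1, params.kappa2, params.kappa_m1, params.kappa_m
    root = math.sqrt((k1 + km1) ** 2 + 4.0 * k1 * k2 * (n - 1))
    return n / (n - 2) + (km1 + k1 - root) / (km * (n - 1))


def q_hat(params: RateConstants) -> float:
    """Cross-links per oligomer at the candidate steady state,
    ``q_hat = (n - (n-2) alpha_bar)/2``; lies in (1, n/2) exactly in the
    finite-size regime."""
    return (params.n - (params.n - 2) * alpha_bar(params)) / 2.0


@dataclass(frozen=True)
class RegimeReport:
    """Outcome of the regime classification for one parameter set."""

    alpha_bar: float
    q_hat: float
    regime: Regime
    boundary: bool
    steady_state: Optional[ContinuumState]
    p_hat: Optional[float]

    def as_dict(self) -> dict:
        ss = None
        if self.steady_state is not None:
            ss = {"p": self.steady_state.p, "q": self.steady_state.q, "r": self.steady_state.r}
        return {
            "alpha_bar": self.alpha_bar,
            "q_hat": self.q_hat,
            "regime": self.regime.value,
            "boundary": self.boundary,
            "steady_state": ss,
            "p_hat": self.p_hat,
        }


@dataclass(frozen=True)
class AsymptoticCoefficients:
    """Leading coefficients of the quadratic-growth regime:
    ``p ~ p1 t``, ``q ~ q2 t^2``, ``r ~ r2 t^2``, ``s ~ s1 t``."""

    p1: float
    q2: float
    r2: float
    s1: float


@dataclass(frozen=True)
class KappaZeroLimits:
    """Limits of the breaking-free (``kappa_m = 0``) dynamics: ``p -> p_inf``,
    ``s -> s_inf``, and asymptotic slopes of ``q`` and ``r``."""

    p_inf: float
    s_inf: float
    slope_q: float
    slope_r: float


def _inequality_classification(params: RateConstants) -> tuple[int, int]:
    """Sign of the two explicit product inequalities on kappa1*kappa2.

    Returns ``(sign(k1 k2 - rhs_stab), sign(k1 k2 - rhs_grow))``:
    ``alpha_bar < 1`` iff the first is positive, ``alpha_bar > 0`` iff the
    second is negative; 0 marks the boundary within tolerance.
    """
    n = params.n
    k1, k2, km1, km = params.kappa1, params.kappa2, params.kappa_m1, params.kappa_m
    lhs = k1 * k2
    rhs_stab = km / (n - 2) * (k1 + (n - 1) / (n - 2) * km + km1)
    rhs_grow = km * n / (2 * (n - 2)) * (k1 + n * (n - 1) / (2 * (n - 2)) * km + km1)

    def sign(a: float, b: float) -> int:
        scale = max(abs(a), abs(b), 1e-300)
        if abs(a - b) <= BOUNDARY_TOL * scale:
            return 0
        return 1 if a > b else -1

    return sign(lhs, rhs_stab), sign(lhs, rhs_grow)


def steady_state(params: RateConstants) -> Optional[ContinuumState]:
    """Closed-form nontrivial steady state, or ``None`` outside the
    finite-size regime (only the origin remains then).

    In the finite-size regime (``0 < alpha_bar < 1``) the state is strictly
    positive, admissible, and the right-hand side vanishes there to
    round-off.
    """
    ab = alpha_bar(params)
    if not (0.0 < ab < 1.0):
        return None
    n = params.n
    k1, k2, k3, km1, km = (
        params.kappa1, params.kappa2, params.kappa3, params.kappa_m1, params.kappa_m,
    )
    qh = (n - (n - 2) * ab) / 2.0
    denom = k3 * (km * qh * (n - 1) + km1 * (n - 2))
    p_bar = k1 * k2 * (n - 2) / denom * (1.0 - ab) / ab
    q_bar = k1 * k2 ** 2 * (n - 2) / (km * denom) * (1.0 - ab) / ab ** 2
    r_bar = q_bar / qh
    return ContinuumState(p_bar, q_bar, r_bar)


def classify_regime(params: RateConstants) -> RegimeReport:
    """Classify the parameter set into the three long-time regimes.

    The classification by the sign pattern of ``alpha_bar`` is cross-checked
    against the algebraically equivalent explicit inequalities on
    ``kappa1 * kappa2``; a disagreement beyond the boundary tolerance would
    indicate a numerical defect and raises.
    """
    ab = alpha_bar(params)
    qh = (params.n - (params.n - 2) * ab) / 2.0

    boundary = False
    if ab >= 1.0 - BOUNDARY_TOL * max(1.0, abs(ab)):
        regime = Regime.EXTINCTION
        boundary = abs(ab - 1.0) <= BOUNDARY_TOL * max(1.0, abs(ab))
    elif ab <= BOUNDARY_TOL * max(1.0, abs(ab)):
        regime = Regime.UNBOUNDED_GROWTH
        boundary = abs(ab) <= BOUNDARY_TOL
    else:
        regime = Regime.FINITE_SIZE

    sign_stab, sign_grow = _inequality_classification(params)
    expected = {
        Regime.EXTINCTION: (-1, -1) if not boundary else (0, -1),
        Regime.FINITE_SIZE: (1, -1),
        Regime.UNBOUNDED_GROWTH: (1, 1) if not boundary else (1, 0),
    }[regime]
    for got, want in zip((sign_stab, sign_grow), expected):
        if want != 0 and got != 0 and got != want:
            raise AssertionError(
                f"inequality cross-check disagrees with alpha_bar = {ab}: "
                f"signs {(sign_stab, sign_grow)}"
            )

    ss = steady_state(params) if regime is Regime.FINITE_SIZE else None
    p_hat = None
    if ss is not None:
        p_hat = params.kappa_m * qh * ab / params.kappa2
    return RegimeReport(
        alpha_bar=ab, q_hat=qh, regime=regime, boundary=boundary,
        steady_state=ss, p_hat=p_hat,
    )


def critical_kappa_minus(params: RateConstants, boundary: str) -> float:
    """Cross-link breaking rate at which the selected regime boundary is hit.

    ``boundary`` is ``"alpha=1"`` (extinction onset) or ``"alpha=0"`` (growth
    onset).  Solves the explicit boundary relation as a quadratic in
    ``kappa_m`` (the value of ``params.kappa_m`` itself is ignored); the
    stable root formula avoids cancellation for small coefficients.
    """
    n = params.n
    k1, k2, km1 = params.kappa1, params.kappa2, params.kappa_m1
    if not (k1 > 0 and k2 > 0 and km1 > 0):
        raise DomainError("critical_kappa_minus requires kappa1, kappa2, kappa_m1 > 0")
    if boundary == "alpha=1":
        a = (n - 1) / (n - 2) ** 2
        b = (k1 + km1) / (n - 2)
    elif boundary == "alpha=0":
        a = n * n * (n - 1) / (4.0 * (n - 2) ** 2)
        b = n * (k1 + km1) / (2.0 * (n - 2))
    else:
        raise DomainError(f"boundary must be 'alpha=1' or 'alpha=0', got {boundary!r}")
    c = k1 * k2
    disc = b * b + 4.0 * a * c
    if not disc > 0:
        raise DomainError("no positive root for the boundary relation")
    return 2.0 * c / (b + math.sqrt(disc))


def asymptotic_coefficients(params: RateConstants) -> AsymptoticCoefficients:
    """Quadratic-growth coefficients, valid when ``alpha_bar < 0``.

    ``p1`` is proportional to the margin by which the growth inequality is
    violated and is positive exactly in the growth regime; ``q2 = (n/2) r2``
    because growing aggregates become fully packed."""
    ab = alpha_bar(params)
    if not ab < 0.0:
        raise DomainError(
            f"asymptotic coefficients require alpha_bar < 0, got {ab}"
        )
    n = params.n
    k1, k2, k3, km1, km = (
        params.kappa1, params.kappa2, params.kappa3, params.kappa_m1, params.kappa_m,
    )
    margin = k1 * k2 - km * n / (2.0 * (n - 2)) * (
        k1 + km1 + km * n * (n - 1) / (2.0 * (n - 2))
    )
    denom = 2.0 * n * k2 + km * n + 4.0 * km1
    p1 = km * n / (k3 * denom) * margin
    q2 = k3 * (n - 2) * denom / (km * (4.0 * k1 * (n - 2) + km * n * n)) * p1 ** 2
    r2 = 2.0 * q2 / n
    s1 = km * q2 / (k3 * p1)
    return AsymptoticCoefficients(p1=p1, q2=q2, r2=r2, s1=s1)


def kappa_zero_limits(params: RateConstants) -> KappaZeroLimits:
    """Limits of the dynamics without cross-link breaking (``kappa_m = 0``):
    ``(p, s)`` solve a closed planar system with a globally attracting
    equilibrium, and the aggregate grows linearly.

    The equilibrium is the intersection of the two nullclines
    ``kappa1 s = (kappa2 + kappa_m1 + kappa3 s) p`` and
    ``((n-1) kappa2 + kappa_m1) p = (kappa1 + kappa3 p) s``:

    .. math::

        p_\\infty = \\frac{(n-2)\\kappa_1\\kappa_2}
                         {\\kappa_3(n\\kappa_2 + 2\\kappa_{-1})},
        \\qquad
        s_\\infty = \\frac{(n-2)\\kappa_2}{2\\kappa_3}.
    """
    if params.kappa_m != 0.0:
        raise DomainError(
            f"kappa_zero_limits requires kappa_m = 0, got {params.kappa_m!r}"
        )
    _require_positive_rates(params, need_kappa_m=False)
    n = params.n
    k1, k2, k3, km1 = params.kappa1, params.kappa2, params.kappa3, params.kappa_m1
    p_inf = (n - 2) * k1 * k2 / (k3 * (n * k2 + 2.0 * km1))
    s_inf = (n - 2) * k2 / (2.0 * k3)
    return KappaZeroLimits(
        p_inf=p_inf,
        s_inf=s_inf,
        slope_q=p_inf * (k2 + k3 * s_inf),
        slope_r=k2 * p_inf,
    )


def lyapunov_value(p: float, s: float, limits: KappaZeroLimits) -> float:
    """Box Lyapunov function of the ``kappa_m = 0`` planar system.

    Returns ``a - 1`` where ``a >= 1`` is the unique scale with ``(p, s)`` on
    the boundary of ``[p_inf/a, a p_inf] x [s_inf/a, a s_inf]``; zero only at
    the equilibrium, strictly decreasing along trajectories.
    """
    if not (p > 0 and s > 0):
        raise DomainError(f"lyapunov_value requires p, s > 0, got ({p!r}, {s!r})")
    a = max(p / limits.p_inf, limits.p_inf / p, s / limits.s_inf, limits.s_inf / s)
    return a - 1.0


def exponent_estimate(
    traj: Trajectory,
    component: str,
    window: tuple[float, float] | None = None,
) -> float:
    """Least-squares slope of ``log(component)`` against ``log(t)`` over a
    time window (default: the final decade of the run).

    For growth-regime parameter sets the slope approaches 1 for ``p`` and 2
    for ``q`` and ``r`` as the window moves to larger times.
    """
    if component not in ("p", "q", "r"):
        raise DomainError(f"component must be one of p, q, r, got {component!r}")
    t_end = float(traj.times[-1])
    if window is None:
        window = (t_end / 10.0, t_end)
    lo, hi = window
    if lo < 10.0:
        raise DomainError("window must start at t >= 10 to exclude the transient")
    mask = (traj.times >= lo) & (traj.times <= hi)
    if int(mask.sum()) < 2:
        raise DomainError("window contains fewer than two trajectory points")
    values = getattr(traj, component)[mask]
    if np.any(values <= 0):
        raise DomainError("component must be strictly positive on the window")
    slope, _ = np.polyfit(np.log(traj.times[mask]), np.log(values), 1)
    return float(slope)
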