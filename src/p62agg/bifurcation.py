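"""Regime boundaries in concentration space and dissociation-constant
estimation.

Under the symmetry assumptions ``kappa1' = kappa2'`` (equal binding
constants) and ``kappa_m1 = kappa_m`` (equal unbinding constants), the whole
parametrization collapses to the concentrations ``[Ubi]`` and ``[p62_n]``
(both in µM) and a single dissociation constant ``K_d = kappa_m1 / kappa1'``
(µM).  The two regime boundaries become explicit curves in the
``([Ubi], [p62_n])`` plane:

* onset of stability (``alpha_bar = 1``):
  ``[p62_n][Ubi] = K_d/(n-2) * ([Ubi] + (2n-3) K_d/(n-2))``,
* onset of unbounded growth (``alpha_bar = 0``):
  ``[p62_n][Ubi] = n K_d/(2(n-2)) * ([Ubi] + (n^2+n-4) K_d/(2(n-2)))``.

Given an onset concentration pair observed in an aggregation experiment,
either relation is a quadratic in ``K_d`` with exactly one positive root —
this inverts the boundary into an estimate of the binding strength.

``alpha_bar`` is invariant under a common rescaling of the four binding and
unbinding rates, so the overall time scale ``kappa1'`` cancels from every
boundary; it is fixed to 1 by default.  ``kappa3`` never enters
``alpha_bar`` and is likewise fixed to 1 for classification purposes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError
from .params import RateConstants
from .regimes import Regime, classify_regime

__all__ = [
    "Branch",
    "ConcentrationPoint",
    "BoundaryBranch",
    "PhaseDiagram",
    "params_from_concentrations",
    "boundary_p62",
    "estimate_kd",
    "kd_vs_n_scan",
    "phase_diagram",
    "plot_phase_diagram",
]


class Branch(str, enum.Enum):
    """Which regime boundary: stability onset (``alpha_bar = 1``) or growth
    onset (``alpha_bar = 0``)."""

    ALPHA_EQ_1 = "alpha1"
    ALPHA_EQ_0 = "alpha0"


def _coerce_branch(which) -> Branch:
    if isinstance(which, Branch):
        return which
    try:
        return Branch(which)
    except ValueError:
        pass
    try:
        return Branch[str(which).upper()]
    except KeyError:
        raise DomainError(f"unknown branch {which!r}; use 'alpha1' or 'alpha0'") from None


@dataclass(frozen=True)
class ConcentrationPoint:
    """A point in concentration space (µM) under the symmetric-rates
    assumption."""

    ubi: float
    p62n: float
    n: int
    kd: float

    def __post_init__(self) -> None:
        if self.ubi < 0 or self.p62n < 0 or self.kd < 0:
            raise DomainError("concentrations and kd must be nonnegative")
        if not (isinstance(self.n, int) and self.n >= 3):
            raise DomainError(f"n must be an integer >= 3, got {self.n!r}")


@dataclass(frozen=True)
class BoundaryBranch:
    which: Branch
    ubi: np.ndarray
    p62n: np.ndarray


@dataclass
class PhaseDiagram:
    """Regime label per grid cell plus the two analytic boundary curves.

    ``labels[iu, ip]`` is the regime at ``(ubi_grid[iu], p62_grid[ip])``;
    ``boundary[iu, ip]`` flags cells whose parameters land exactly on a
    regime boundary (within the classification tolerance).
    """

    ubi_grid: np.ndarray
    p62_grid: np.ndarray
    labels: np.ndarray  # dtype object, Regime values
    boundary: np.ndarray  # bool
    branch_alpha1: BoundaryBranch
    branch_alpha0: BoundaryBranch
    kd: float
    n: int


def params_from_concentrations(
    point: ConcentrationPoint,
    kappa1_prime: float = 1.0,
    kappa3: float = 1.0,
) -> RateConstants:
    """Rate constants implied by a concentration point.

    ``kappa1 = kappa1' [Ubi]``, ``kappa2 = kappa1' [p62_n]`` (equal binding
    constants), ``kappa_m1 = kappa_m = K_d kappa1'`` (equal unbinding
    constants).  ``alpha_bar`` of the result is independent of the
    ``kappa1'`` time scale.
    """
    if not kappa1_prime > 0 or not kappa3 > 0:
        raise DomainError("kappa1_prime and kappa3 must be positive")
    unbind = point.kd * kappa1_prime
    return RateConstants(
        n=point.n,
        kappa1=kappa1_prime * point.ubi,
        kappa2=kappa1_prime * point.p62n,
        kappa3=kappa3,
        kappa_m1=unbind,
        kappa_m=unbind,
    )


def boundary_p62(ubi: float, kd: float, n: int, which) -> float:
    """Oligomer concentration on the selected regime boundary at cross-linker
    concentration ``ubi`` (all µM).

    Large-``ubi`` asymptotes: ``K_d/(n-2)`` for the stability onset and
    ``n K_d/(2(n-2))`` for the growth onset — below those levels the
    respective transition is impossible however much cross-linker there is.
    """
    branch = _coerce_branch(which)
    if not ubi > 0 or not kd > 0:
        raise DomainError("ubi and kd must be positive")
    if branch is Branch.ALPHA_EQ_1:
        return kd / ((n - 2) * ubi) * (ubi + (2 * n - 3) * kd / (n - 2))
    return n * kd / (2 * (n - 2) * ubi) * (ubi + (n * n + n - 4) * kd / (2 * (n - 2)))


def _quadratic_coefficients(ubi: float, p62n: float, n: int, branch: Branch):
    """Coefficients (a, b, c) of ``a Kd^2 + b Kd - c = 0`` for the boundary
    relation at the given concentrations."""
    if branch is Branch.ALPHA_EQ_1:
        a = (2 * n - 3) / (n - 2) ** 2
        b = ubi / (n - 2)
    else:
        a = n * (n * n + n - 4) / (4.0 * (n - 2) ** 2)
        b = n * ubi / (2.0 * (n - 2))
    return a, b, p62n * ubi


def estimate_kd(ubi: float, p62n: float, n: int, which) -> float:
    """Dissociation constant (µM) for which the given concentrations lie on
    the selected regime boundary.

    The unique positive root of the boundary quadratic, evaluated with the
    cancellation-stable formula ``Kd = 2c / (b + sqrt(b^2 + 4ac))``;
    round-trips through :func:`boundary_p62`.  ``p62n = 0`` degenerates to 0.
    """
    branch = _coerce_branch(which)
    if not ubi > 0 or p62n < 0:
        raise DomainError("ubi must be positive and p62n nonnegative")
    if p62n == 0.0:
        return 0.0
    a, b, c = _quadratic_coefficients(ubi, p62n, n, branch)
    disc = b * b + 4.0 * a * c
    assert disc > 0.0  # a, c > 0 for positive inputs
    return 2.0 * c / (b + math.sqrt(disc))


def kd_vs_n_scan(
    ubi: float,
    p62n: float,
    n_range: Sequence[int],
) -> dict[str, np.ndarray]:
    """``K_d`` estimates across oligomer sizes at fixed onset concentrations.

    For large ``n`` the stability-onset branch grows like ``n^(1/2)`` and
    the growth-onset branch decays like ``n^(-1/2)`` (read off the quadratic
    coefficients: ``a = O(1)`` vs ``a = O(n)`` with ``c`` fixed).
    """
    n_arr = np.asarray(list(n_range), dtype=int)
    if np.any(n_arr < 3) or np.any(n_arr > 1024):
        raise DomainError("n_range must lie within [3, 1024]")
    kd1 = np.array([estimate_kd(ubi, p62n, int(n), Branch.ALPHA_EQ_1) for n in n_arr])
    kd0 = np.array([estimate_kd(ubi, p62n, int(n), Branch.ALPHA_EQ_0) for n in n_arr])
    return {"n": n_arr, "kd_alpha1": kd1, "kd_alpha0": kd0}


def phase_diagram(
    kd: float,
    n: int,
    ubi_grid: Sequence[float],
    p62_grid: Sequence[float],
) -> PhaseDiagram:
    """Regime label at every grid point of the concentration plane.

    Cells below the stability-onset curve are extinction, above the
    growth-onset curve unbounded growth, and finite size in between; along
    any vertical line the ordering is extinction -> finite size -> growth
    because ``alpha_bar`` decreases strictly with the oligomer supply.
    """
    ubi_arr = np.asarray(ubi_grid, dtype=float)
    p62_arr = np.asarray(p62_grid, dtype=float)
    if np.any(ubi_arr <= 0) or np.any(p62_arr <= 0):
        raise DomainError("grids must be strictly positive")
    labels = np.empty((len(ubi_arr), len(p62_arr)), dtype=object)
    boundary = np.zeros((len(ubi_arr), len(p62_arr)), dtype=bool)
    for iu, ubi in enumerate(ubi_arr):
        for ip, p62n in enumerate(p62_arr):
            report = classify_regime(
                params_from_concentrations(ConcentrationPoint(ubi, p62n, n, kd))
            )
            labels[iu, ip] = report.regime
            boundary[iu, ip] = report.boundary
    b1 = np.array([boundary_p62(u, kd, n, Branch.ALPHA_EQ_1) for u in ubi_arr])
    b0 = np.array([boundary_p62(u, kd, n, Branch.ALPHA_EQ_0) for u in ubi_arr])
    return PhaseDiagram(
        ubi_grid=ubi_arr,
        p62_grid=p62_arr,
        labels=labels,
        boundary=boundary,
        branch_alpha1=BoundaryBranch(Branch.ALPHA_EQ_1, ubi_arr, b1),
        branch_alpha0=BoundaryBranch(Branch.ALPHA_EQ_0, ubi_arr, b0),
        kd=kd,
        n=n,
    )


def plot_phase_diagram(diagram: PhaseDiagram, path) -> None:
    """Render the phase diagram with its two boundary curves to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = {Regime.EXTINCTION: 0, Regime.FINITE_SIZE: 1, Regime.UNBOUNDED_GROWTH: 2}
    z = np.vectorize(order.get)(diagram.labels).T
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.pcolormesh(
        diagram.ubi_grid, diagram.p62_grid, z,
        shading="nearest", cmap="viridis", vmin=0, vmax=2, alpha=0.6,
    )
    ax.plot(diagram.branch_alpha1.ubi, diagram.branch_alpha1.p62n,
            "k-", label="stability onset")
    ax.plot(diagram.branch_alpha0.ubi, diagram.branch_alpha0.p62n,
            "k--", label="growth onset")
    ax.set_xlabel("[Ubi] (µM)")
    ax.set_ylabel("[p62$_n$] (µM)")
    ax.set_ylim(float(diagram.p62_grid[0]), float(diagram.p62_grid[-1]))
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
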