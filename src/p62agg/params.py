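"""Rate constants of the aggregation scheme.

The model has two description levels that share one parameter set:

* the **discrete** level, where an aggregate is a triplet ``(i, j, k)`` of
  one-hand bound cross-linkers, both-hand bound cross-linkers and p62
  oligomers, and the compactification reaction is second order with constant
  kappa3' (per pair per time);
* the **continuum** level, obtained by scaling counts with a large typical
  size ``k0`` (``p = i/k0`` etc.), where the compactification constant
  appears as ``kappa3 = kappa3' * k0``.

``RateConstants.kappa3`` always stores the constant appropriate to the level
the object is used at; the conversion between levels is explicit through
:func:`to_discrete` / :func:`to_continuum` and never implicit, because the two
constants differ by the factor ``k0``.

kappa1 and kappa2 are the pseudo-first-order constants kappa1'*[Ubi] and
kappa2'*[p62_n] — the free-particle pools are assumed abundant and constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import DomainError

__all__ = ["RateConstants", "to_discrete", "to_continuum"]


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameters of the cross-linking scheme.

    Parameters
    ----------
    n:
        Oligomer size: number of ubiquitin binding sites per p62 oligomer.
        Must be an integer >= 3 (two sites cannot sustain a branched
        aggregate).
    kappa1:
        Ubiquitin-addition rate, ``kappa1' * [Ubi]`` (per time per free site).
    kappa2:
        Oligomer-addition rate, ``kappa2' * [p62_n]`` (per time per one-hand
        bound cross-linker).
    kappa3:
        Compactification constant. At the continuum level this is
        ``kappa3' * k0``; at the discrete level the second-order ``kappa3'``.
    kappa_m1:
        Unbinding rate of a one-hand bound cross-linker (per time).
    kappa_m:
        Cross-link breaking rate (per time per both-hand bound cross-linker).
    """

    n: int
    kappa1: float
    kappa2: float
    kappa3: float
    kappa_m1: float
    kappa_m: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n, int) and not isinstance(self.n, bool)):
            raise DomainError(f"oligomer size n must be an integer, got {self.n!r}")
        if self.n < 3:
            raise DomainError(f"oligomer size n must be >= 3, got {self.n}")
        for name in ("kappa1", "kappa2", "kappa3", "kappa_m1", "kappa_m"):
            value = getattr(self, name)
            if not value >= 0.0:
                raise DomainError(f"rate constant {name} must be >= 0, got {value!r}")

    def replace(self, **changes) -> "RateConstants":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "kappa1": self.kappa1,
            "kappa2": self.kappa2,
            "kappa3": self.kappa3,
            "kappa_m1": self.kappa_m1,
            "kappa_m": self.kappa_m,
        }


def to_discrete(params: RateConstants, k0: float) -> RateConstants:
    """Convert a continuum parameter set to the discrete level.

    Replaces ``kappa3`` (continuum) by the second-order ``kappa3' = kappa3/k0``
    used in the discrete propensities.
    """
    if not k0 > 0:
        raise DomainError(f"k0 must be positive, got {k0!r}")
    return params.replace(kappa3=params.kappa3 / k0)


def to_continuum(params: RateConstants, k0: float) -> RateConstants:
    """Convert a discrete parameter set (kappa3 = kappa3') to the continuum
    level, where ``kappa3 = kappa3' * k0``."""
    if not k0 > 0:
        raise DomainError(f"k0 must be positive, got {k0!r}")
    return params.replace(kappa3=params.kappa3 * k0)
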