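"""Parameters, state, payoffs and vector field of the feedback-evolving commons game.

The model couples replicator dynamics for the fraction ``x`` of cooperators
(law-abiding harvesters) with logistic growth of a renewable common-pool
resource ``y``:

.. math::

    \\dot x &= x(1-x)\\,(P_L - P_V) \\\\
    \\dot y &= r y (1 - y/R_m) - N\\,[b_l x + (1-x) b_v]

where the legal per-capita harvest is ``b_l = b_m y / R_m``, a violator takes
``b_v = b_l (1+\\alpha)``, and payoffs are ``P_L = b_l`` and
``P_V = b_v - p\\beta`` (a violator is detected with probability ``p`` per unit
time and fined ``\\beta``).  Substituting the payoffs gives the two-dimensional
system

.. math::

    \\dot x &= x(1-x)\\,\\bigl(p\\beta - \\tfrac{y}{R_m} b_m \\alpha\\bigr) \\\\
    \\dot y &= r y (1 - y/R_m) - N \\tfrac{y}{R_m} b_m [1 + (1-x)\\alpha]

This module holds the parameter container, the phase-plane state, the payoff
primitives and both the generic and substituted forms of the vector field.
Stochastic (per-agent) detection lives in :mod:`commonsgame.abm`; here the
fine enters only through its expectation ``p * beta``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

logger = logging.getLogger("commonsgame")

__all__ = [
    "ModelParams",
    "SystemState",
    "DerivedRates",
    "legal_share",
    "violator_share",
    "payoffs",
    "derived_rates",
    "vector_field",
    "replicator_rhs",
    "resource_rhs",
]


@dataclass(frozen=True)
class ModelParams:
    """The seven constants of the commons game.

    Parameters
    ----------
    r : float
        Intrinsic growth rate of the renewable resource, per unit time (> 0).
    R_m : float
        Carrying capacity of the resource pool, in resource units (> 0).
    N : int
        Number of individuals in the community (positive integer).
    b_m : float
        Maximal per-capita allocation when the pool is full, resource units
        per unit time (> 0).  Sustainable sharing suggests ``b_m <= R_m/N``;
        violating that bound is allowed but logged as a warning.
    alpha : float
        Severity of defection (> 0): a violator harvests ``(1+alpha)`` times
        the legal share.
    p : float
        Probability of detecting a violator during one time unit, in (0, 1).
    beta : float
        Fine subtracted from a detected violator's payoff (> 0).
    permissive : bool
        If True, allow the edge values ``p in {0, 1}`` and ``beta = 0`` for
        parameter sweeps; the resulting dynamics may be non-hyperbolic.
    """

    r: float
    R_m: float
    N: int
    b_m: float
    alpha: float
    p: float
    beta: float
    permissive: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("r", "R_m", "b_m", "alpha"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(f"{name} must be a finite positive number, got {value!r}")
        if not (isinstance(self.N, (int,)) and self.N >= 1):
            raise ValueError(f"N must be a positive integer, got {self.N!r}")
        if self.permissive:
            if not (0.0 <= self.p <= 1.0):
                raise ValueError(f"p must lie in [0, 1], got {self.p!r}")
            if self.beta < 0:
                raise ValueError(f"beta must be non-negative, got {self.beta!r}")
            if self.p in (0.0, 1.0) or self.beta == 0.0:
                logger.warning(
                    "permissive parameters: p=%g, beta=%g sit on the boundary of "
                    "their admissible ranges; equilibria may be non-hyperbolic",
                    self.p,
                    self.beta,
                )
        else:
            if not (0.0 < self.p < 1.0):
                raise ValueError(f"p must lie strictly in (0, 1), got {self.p!r}")
            if not (self.beta > 0):
                raise ValueError(f"beta must be strictly positive, got {self.beta!r}")
        if self.b_m > self.R_m / self.N:
            logger.warning(
                "b_m=%g exceeds R_m/N=%g: the nominal per-capita limit is larger "
                "than an equal split of a full pool",
                self.b_m,
                self.R_m / self.N,
            )

    @property
    def p_beta(self) -> float:
        """Expected fine rate ``p * beta``."""
        return self.p * self.beta

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        """Flat key -> number mapping used by config/serialization layers."""
        return {
            "r": self.r,
            "R_m": self.R_m,
            "N": self.N,
            "b_m": self.b_m,
            "alpha": self.alpha,
            "p": self.p,
            "beta": self.beta,
        }

    @classmethod
    def from_dict(cls, data: dict, permissive: bool = False) -> "ModelParams":
        known = {"r", "R_m", "N", "b_m", "alpha", "p", "beta"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = known - set(data)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(
            r=float(data["r"]),
            R_m=float(data["R_m"]),
            N=int(data["N"]),
            b_m=float(data["b_m"]),
            alpha=float(data["alpha"]),
            p=float(data["p"]),
            beta=float(data["beta"]),
            permissive=permissive,
        )


class SystemState(NamedTuple):
    """A point of the phase plane: cooperator fraction and resource stock."""

    x: float  # fraction of cooperators, in [0, 1]
    y: float  # resource abundance, >= 0, in resource units

    def validate(self) -> "SystemState":
        if not (0.0 <= self.x <= 1.0):
            raise ValueError(f"cooperator fraction x must lie in [0, 1], got {self.x!r}")
        if self.y < 0:
            raise ValueError(f"resource abundance y must be non-negative, got {self.y!r}")
        return self


class DerivedRates(NamedTuple):
    """Per-capita gain rates and the regime thresholds built from them.

    ``e_c = b_m N / R_m`` and ``e_d = e_c (1 + alpha)`` are the population
    draw rates under full cooperation and full defection; comparing the
    intrinsic growth rate ``r`` against them separates the slow, moderate and
    rapid growth regimes.  ``tau_c = b_m alpha (1 - e_c/r)`` and
    ``tau_d = b_m alpha (1 - e_d/r)`` are the ``p*beta`` thresholds that the
    expected fine must exceed for full cooperation (resp. coexistence).
    """

    e_c: float
    e_d: float
    p_beta: float
    tau_c: float
    tau_d: float


def legal_share(params: ModelParams, y: float) -> float:
    """Legal per-capita allocation ``b_l = b_m * y / R_m``; linear in ``y``."""
    if y < 0:
        raise ValueError(f"resource amount y must be non-negative, got {y!r}")
    return params.b_m * y / params.R_m


def violator_share(params: ModelParams, y: float) -> float:
    """A violator's harvest ``b_v = b_l * (1 + alpha)``."""
    return legal_share(params, y) * (1.0 + params.alpha)


def payoffs(params: ModelParams, y: float) -> tuple[float, float]:
    """Expected payoffs ``(P_L, P_V)`` at resource level ``y``.

    The cooperator keeps the legal share; the violator takes the inflated
    share but pays the fine with probability ``p``, so in expectation
    ``P_V = b_v - p*beta``, which may be negative.
    """
    p_l = legal_share(params, y)
    p_v = violator_share(params, y) - params.p * params.beta
    return p_l, p_v


def derived_rates(params: ModelParams) -> DerivedRates:
    """Gain rates ``e_c``, ``e_d`` and the ``p*beta`` regime thresholds."""
    e_c = params.b_m * params.N / params.R_m
    e_d = e_c * (1.0 + params.alpha)
    tau_c = params.b_m * params.alpha * (1.0 - e_c / params.r)
    tau_d = params.b_m * params.alpha * (1.0 - e_d / params.r)
    return DerivedRates(e_c=e_c, e_d=e_d, p_beta=params.p_beta, tau_c=tau_c, tau_d=tau_d)


def replicator_rhs(params: ModelParams, state: SystemState) -> float:
    """Generic replicator equation ``x(1-x)(P_L - P_V)`` built from payoffs."""
    p_l, p_v = payoffs(params, state.y)
    return state.x * (1.0 - state.x) * (p_l - p_v)


def resource_rhs(params: ModelParams, state: SystemState) -> float:
    """Generic resource equation: logistic growth minus total consumption."""
    x, y = state
    growth = params.r * y * (1.0 - y / params.R_m)
    consumption = params.N * (
        legal_share(params, y) * x + violator_share(params, y) * (1.0 - x)
    )
    return growth - consumption


def vector_field(params: ModelParams, state: SystemState) -> tuple[float, float]:
    """Time derivatives ``(dx/dt, dy/dt)`` of the substituted 2-D system.

    Algebraically identical to composing the generic replicator and resource
    equations with the payoff definitions (property-tested):

    ``dx/dt = x(1-x)(p*beta - (y/R_m) b_m alpha)``
    ``dy/dt = r y (1 - y/R_m) - N (y/R_m) b_m [1 + (1-x) alpha]``
    """
    x, y = state
    y_rel = y / params.R_m
    dx_dt = x * (1.0 - x) * (params.p_beta - y_rel * params.b_m * params.alpha)
    dy_dt = params.r * y * (1.0 - y_rel) - params.N * y_rel * params.b_m * (
        1.0 + (1.0 - x) * params.alpha
    )
    return dx_dt, dy_dt
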