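"""Closed-form equilibria, Jacobian stability analysis, and regime labels.

The substituted system has at most five fixed points:

* ``(0, 0)`` — full defection, depleted pool (*origin*),
* ``(0, R_m - b_m N (1+alpha)/r)`` — full defection at a sustainable level
  (*defector_boundary*),
* ``(1, 0)`` — full cooperation, depleted pool (*coop_depleted*),
* ``(1, R_m - b_m N / r)`` — full cooperation at a sustainable level
  (*coop_interior*),
* the interior coexistence point with ``y* = p beta R_m / (b_m alpha)`` and
  ``x* = 1 + 1/alpha - R_m r/(alpha b_m N) + p beta R_m r/(alpha^2 b_m^2 N)``.

Only candidates inside the physical domain ``0 <= x <= 1``, ``y >= 0`` are
admissible.  Stability follows from the eigenvalues of the Jacobian; the four
boundary Jacobians are triangular, so their eigenvalues are the diagonal
entries.  Which point attracts the dynamics is decided by how the intrinsic
growth rate ``r`` compares with the gain rates ``e_c < e_d``, and by the
expected fine ``p*beta`` against the thresholds ``tau_c`` and ``tau_d``.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass

import numpy as np

from .model_core import ModelParams, SystemState, derived_rates, vector_field

__all__ = [
    "FixedPointFamily",
    "Stability",
    "FixedPointReport",
    "GrowthClass",
    "Outcome",
    "RegimeLabel",
    "jacobian",
    "classify_stability",
    "enumerate_fixed_points",
    "classify_regime",
    "reports_to_json",
]

#: Default relative tolerance deciding hyperbolicity of an eigenvalue.
HYPERBOLICITY_RTOL = 1e-9

#: Relative tolerance for merging coincident fixed-point candidates.
DEDUP_RTOL = 1e-12


class FixedPointFamily(str, enum.Enum):
    origin = "origin"
    defector_boundary = "defector_boundary"
    coop_depleted = "coop_depleted"
    coop_interior = "coop_interior"
    interior = "interior"


class Stability(str, enum.Enum):
    stable = "stable"
    unstable = "unstable"
    saddle = "saddle"
    non_hyperbolic = "non_hyperbolic"

    @property
    def is_unstable(self) -> bool:
        """Saddles count as unstable for regime bookkeeping: almost every
        trajectory leaves them."""
        return self in (Stability.unstable, Stability.saddle)


@dataclass(frozen=True)
class FixedPointReport:
    """An equilibrium with its linearization and stability verdict."""

    location: SystemState
    family: FixedPointFamily
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    stability: Stability

    def to_dict(self) -> dict:
        return {
            "x": self.location.x,
            "y": self.location.y,
            "family": self.family.value,
            "jacobian": [list(row) for row in self.jacobian.tolist()],
            "eigenvalues": [
                {"real": float(ev.real), "imag": float(ev.imag)}
                for ev in self.eigenvalues
            ],
            "stability": self.stability.value,
        }


class GrowthClass(str, enum.Enum):
    slow = "slow"  # r < e_c: pool recovers slower than full cooperation draws
    moderate = "moderate"  # e_c < r < e_d
    rapid = "rapid"  # r > e_d: pool outgrows even full defection
    boundary = "boundary"


class Outcome(str, enum.Enum):
    full_cooperation_depleted = "full_cooperation_depleted"
    full_cooperation_sustainable = "full_cooperation_sustainable"
    coexistence = "coexistence"
    full_defection_sustainable = "full_defection_sustainable"
    boundary_case = "boundary_case"


@dataclass(frozen=True)
class RegimeLabel:
    growth_class: GrowthClass
    outcome: Outcome
    predicted_attractor: SystemState | None

    def to_dict(self) -> dict:
        return {
            "growth_class": self.growth_class.value,
            "outcome": self.outcome.value,
            "predicted_attractor": (
                None
                if self.predicted_attractor is None
                else {"x": self.predicted_attractor.x, "y": self.predicted_attractor.y}
            ),
        }


def jacobian(params: ModelParams, state: SystemState) -> np.ndarray:
    """Jacobian of the substituted vector field at an arbitrary state.

    ``J11 = (1-2x)(p beta - alpha b_m y/R_m)``,
    ``J12 = alpha b_m x(x-1)/R_m``,
    ``J21 = alpha b_m N y/R_m``,
    ``J22 = r - 2 r y/R_m - b_m N (1 + alpha - alpha x)/R_m``.
    """
    x, y = state
    a, bm, rm = params.alpha, params.b_m, params.R_m
    j11 = (1.0 - 2.0 * x) * (params.p_beta - a * bm * y / rm)
    j12 = a * bm * x * (x - 1.0) / rm
    j21 = a * bm * params.N * y / rm
    j22 = params.r - 2.0 * params.r * y / rm - bm * params.N * (1.0 + a - a * x) / rm
    return np.array([[j11, j12], [j21, j22]], dtype=float)


def classify_stability(
    eigenvalues: np.ndarray, tol: float = HYPERBOLICITY_RTOL
) -> Stability:
    """Stability label from the signs of the eigenvalue real parts.

    The tolerance is scaled by ``max(1, spectral radius)`` so that "zero real
    part" is judged relative to the magnitude of the linearization.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=complex)
    scale = max(1.0, float(np.max(np.abs(eigenvalues), initial=0.0)))
    re = eigenvalues.real
    if np.any(np.abs(re) <= tol * scale):
        return Stability.non_hyperbolic
    if np.all(re < 0):
        return Stability.stable
    if np.all(re > 0):
        return Stability.unstable
    return Stability.saddle


def _interior_candidate(params: ModelParams) -> SystemState:
    a, bm, rm, n, r = params.alpha, params.b_m, params.R_m, params.N, params.r
    pb = params.p_beta
    y_star = pb * rm / (bm * a)
    x_star = 1.0 + 1.0 / a - rm * r / (a * bm * n) + pb * rm * r / (a**2 * bm**2 * n)
    return SystemState(x_star, y_star)


def _candidates(params: ModelParams) -> list[tuple[FixedPointFamily, SystemState]]:
    rm, bm, n, r, a = params.R_m, params.b_m, params.N, params.r, params.alpha
    return [
        (FixedPointFamily.origin, SystemState(0.0, 0.0)),
        (FixedPointFamily.defector_boundary, SystemState(0.0, rm - bm * n * (1.0 + a) / r)),
        (FixedPointFamily.coop_depleted, SystemState(1.0, 0.0)),
        (FixedPointFamily.coop_interior, SystemState(1.0, rm - bm * n / r)),
        (FixedPointFamily.interior, _interior_candidate(params)),
    ]


def enumerate_fixed_points(
    params: ModelParams, tol: float = HYPERBOLICITY_RTOL
) -> list[FixedPointReport]:
    """All admissible equilibria with Jacobians, eigenvalues and stability.

    Candidates outside ``0 <= x <= 1`` or ``y < 0`` are discarded; candidates
    that coincide (within a relative tolerance, in ``(x, y/R_m)`` coordinates)
    are merged keeping the boundary-family label, so the count never exceeds
    five.
    """
    admissible: list[tuple[FixedPointFamily, SystemState]] = []
    for family, loc in _candidates(params):
        if -0.0 <= loc.x <= 1.0 and loc.y >= 0.0:
            admissible.append((family, loc))

    # merge coincident candidates; earlier (boundary) families take precedence
    merged: list[tuple[FixedPointFamily, SystemState]] = []
    for family, loc in admissible:
        duplicate = False
        for _, kept in merged:
            scale = max(1.0, abs(kept.x), abs(loc.x))
            same_x = abs(loc.x - kept.x) <= DEDUP_RTOL * scale
            yscale = max(1.0, abs(kept.y) / params.R_m, abs(loc.y) / params.R_m)
            same_y = abs(loc.y - kept.y) / params.R_m <= DEDUP_RTOL * yscale
            if same_x and same_y:
                duplicate = True
                break
        if not duplicate:
            merged.append((family, loc))

    reports = []
    for family, loc in merged:
        jac = jacobian(params, loc)
        eig = np.linalg.eigvals(jac)
        reports.append(
            FixedPointReport(
                location=loc,
                family=family,
                jacobian=jac,
                eigenvalues=eig,
                stability=classify_stability(eig, tol=tol),
            )
        )
    return reports


def classify_regime(params: ModelParams, tol: float = HYPERBOLICITY_RTOL) -> RegimeLabel:
    """Analytic outcome label on the ``(r, p*beta)`` plane.

    Decision rule (ties within tolerance are flagged as boundary cases and
    left to numerical integration):

    * ``r < e_c`` — the pool cannot keep up even with full cooperation:
      cooperators take over but the resource is depleted, attractor ``(1, 0)``.
    * ``p*beta > tau_c`` — inspection/punishment strong enough for full
      cooperation at a sustainable level ``(1, R_m - b_m N/r)``.
    * ``tau_d < p*beta < tau_c`` — coexistence at the interior point.
    * ``p*beta < tau_d`` (possible only for ``r > e_d``) — full defection,
      sustained by the rapid regrowth: ``(0, R_m - b_m N(1+alpha)/r)``.
    """
    if params.p_beta <= 0:
        raise ValueError(
            "classify_regime requires p*beta > 0; the zero-fine limit is "
            "non-hyperbolic and outside the analytic classification"
        )
    rates = derived_rates(params)
    r, pb = params.r, params.p_beta

    def close(u: float, v: float) -> bool:
        return abs(u - v) <= tol * max(1.0, abs(u), abs(v))

    on_growth_boundary = close(r, rates.e_c) or close(r, rates.e_d)
    on_fine_boundary = close(pb, rates.tau_c) or close(pb, rates.tau_d)

    if r < rates.e_c:
        growth = GrowthClass.slow
    elif r < rates.e_d:
        growth = GrowthClass.moderate
    else:
        growth = GrowthClass.rapid
    if on_growth_boundary:
        growth = GrowthClass.boundary

    if on_growth_boundary or on_fine_boundary:
        return RegimeLabel(growth, Outcome.boundary_case, None)

    rm, bm, n, a = params.R_m, params.b_m, params.N, params.alpha
    if r < rates.e_c:
        return RegimeLabel(growth, Outcome.full_cooperation_depleted, SystemState(1.0, 0.0))
    if pb > rates.tau_c:
        return RegimeLabel(
            growth,
            Outcome.full_cooperation_sustainable,
            SystemState(1.0, rm - bm * n / r),
        )
    if pb > rates.tau_d:
        return RegimeLabel(growth, Outcome.coexistence, _interior_candidate(params))
    return RegimeLabel(
        growth,
        Outcome.full_defection_sustainable,
        SystemState(0.0, rm - bm * n * (1.0 + a) / r),
    )


def reports_to_json(
    params: ModelParams,
    reports: list[FixedPointReport],
    regime: RegimeLabel | None = None,
    indent: int = 2,
) -> str:
    """Serialize an equilibrium analysis to a JSON document."""
    doc = {
        "params": params.to_dict(),
        "fixed_points": [rep.to_dict() for rep in reports],
        "n_fixed_points": len(reports),
    }
    if regime is not None:
        doc["regime"] = regime.to_dict()
    return json.dumps(doc, indent=indent)
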