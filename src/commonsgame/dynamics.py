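"""Numerical integration, attractor detection, and (r, p*beta) sweeps.

The coupled system is smooth and non-stiff at the scales of interest, so an
adaptive explicit Runge-Kutta method (``scipy.integrate.solve_ivp`` RK45)
with tight tolerances is used throughout.  Convergence is declared from the
vector-field norm — not from state stagnation, which false-positives on slow
manifolds — and terminal states are matched against the closed-form
equilibria of :mod:`commonsgame.equilibria`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import __version__
from .model_core import ModelParams, SystemState, vector_field
from .equilibria import (
    FixedPointReport,
    Outcome,
    RegimeLabel,
    classify_regime,
    enumerate_fixed_points,
)

logger = logging.getLogger("commonsgame")

__all__ = [
    "Trajectory",
    "PhaseDiagram",
    "IntegrationError",
    "ConsistencyError",
    "integrate",
    "find_attractor",
    "phase_portrait",
    "sweep_phase_diagram",
    "trajectory_to_csv",
    "phase_diagram_to_csv",
]

#: Convergence: ||vector_field||_inf below this times max(1, R_m).
CONVERGENCE_RTOL = 1e-8

#: Attractor matching tolerance in scaled (x, y/R_m) coordinates — far above
#: solver error, far below inter-equilibrium distances at typical parameters.
MATCH_TOL = 1e-3

#: Post-step clamping beyond this magnitude (relative) is reported.
CLAMP_WARN = 1e-9

DEFAULT_T_MAX = 2000.0
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the partial trajectory."""

    def __init__(self, message: str, partial: "Trajectory | None" = None):
        super().__init__(message)
        self.partial = partial


class ConsistencyError(RuntimeError):
    """Raised when a dynamics cross-check contradicts the analytic label."""

    def __init__(self, message: str, cell: tuple | None = None):
        super().__init__(message)
        self.cell = cell


@dataclass
class Trajectory:
    """Time-stamped solution of the coupled ODE system."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 2): columns x, y
    converged: bool
    params: ModelParams

    @property
    def terminal_state(self) -> SystemState:
        return SystemState(float(self.states[-1, 0]), float(self.states[-1, 1]))

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PhaseDiagram:
    """Regime labels over an (r, p*beta) grid, with verification bookkeeping."""

    r_grid: np.ndarray
    p_beta_grid: np.ndarray
    labels: list[list[RegimeLabel]]  # indexed [i_r][j_pb]
    verification_mask: np.ndarray  # True where cross-checked by integration
    template: ModelParams


def _rhs(params: ModelParams):
    def fun(t: float, z: np.ndarray):
        return vector_field(params, SystemState(z[0], z[1]))

    return fun


def _project(states: np.ndarray, params: ModelParams) -> np.ndarray:
    """Clamp floating-point drift back into x in [0,1], y >= 0."""
    clipped = states.copy()
    clipped[:, 0] = np.clip(clipped[:, 0], 0.0, 1.0)
    clipped[:, 1] = np.maximum(clipped[:, 1], 0.0)
    drift = np.max(
        np.abs(clipped - states) / np.array([1.0, max(1.0, params.R_m)]), initial=0.0
    )
    if drift > CLAMP_WARN:
        logger.warning("state projection clamped drift of magnitude %.3e", drift)
    return clipped


def integrate(
    params: ModelParams,
    initial: SystemState,
    t_max: float = DEFAULT_T_MAX,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the coupled system from ``initial`` for ``t_max`` time units.

    ``converged`` is True when the sup-norm of the vector field at the final
    state falls below ``1e-8 * max(1, R_m)``.

    Raises
    ------
    IntegrationError
        If the adaptive solver fails (e.g. step underflow); the partial
        trajectory accumulated so far is attached to the exception.
    """
    initial = SystemState(*initial).validate()
    if not t_max > 0:
        raise ValueError(f"t_max must be positive, got {t_max!r}")
    # y is measured in resource units, so its absolute tolerance scales with R_m
    atol_vec = [atol, atol * max(1.0, params.R_m)]
    sol = solve_ivp(
        _rhs(params),
        (0.0, t_max),
        [initial.x, initial.y],
        method="RK45",
        rtol=rtol,
        atol=atol_vec,
        dense_output=False,
    )
    states = _project(sol.y.T, params)
    if sol.status == -1:
        partial = Trajectory(times=sol.t, states=states, converged=False, params=params)
        raise IntegrationError(f"ODE solver failed: {sol.message}", partial=partial)
    terminal = SystemState(float(states[-1, 0]), float(states[-1, 1]))
    residual = np.abs(vector_field(params, terminal))
    converged = bool(np.max(residual) < CONVERGENCE_RTOL * max(1.0, params.R_m))
    return Trajectory(times=sol.t, states=states, converged=converged, params=params)


def find_attractor(
    params: ModelParams,
    initial: SystemState,
    t_max: float = DEFAULT_T_MAX,
    max_total_time: float = 64 * DEFAULT_T_MAX,
    match_tol: float = MATCH_TOL,
) -> tuple[SystemState, FixedPointReport | None]:
    """Integrate to convergence and match the terminal state to an equilibrium.

    Integration restarts from the running terminal state with a doubled
    horizon until the vector-field norm test passes or ``max_total_time`` is
    exhausted (slowly decaying spirals near weak-fine interior points need
    long horizons).  Matching is done in scaled ``(x, y/R_m)`` coordinates;
    ``None`` is returned (and a warning logged) when no equilibrium lies
    within ``match_tol``.
    """
    state = SystemState(*initial).validate()
    elapsed, horizon = 0.0, t_max
    traj = integrate(params, state, t_max=horizon)
    elapsed += horizon
    while not traj.converged and elapsed < max_total_time:
        horizon = min(2 * horizon, max_total_time - elapsed)
        traj = integrate(params, traj.terminal_state, t_max=horizon)
        elapsed += horizon
    terminal = traj.terminal_state
    scale = np.array([1.0, params.R_m])
    best, best_dist = None, np.inf
    for report in enumerate_fixed_points(params):
        dist = np.max(
            np.abs(
                (np.array(terminal) - np.array(report.location)) / scale
            )
        )
        if dist < best_dist:
            best, best_dist = report, dist
    if best is not None and best_dist <= match_tol:
        return terminal, best
    logger.warning(
        "terminal state (%.6g, %.6g) matches no equilibrium within %.1e "
        "(closest at distance %.3e); converged=%s",
        terminal.x,
        terminal.y,
        match_tol,
        best_dist,
        traj.converged,
    )
    return terminal, None


def phase_portrait(
    params: ModelParams,
    grid: Iterable[SystemState],
    t_max: float = DEFAULT_T_MAX,
) -> list[Trajectory]:
    """One trajectory per initial condition, for plotting in (x, y/R_m).

    Individual integration failures are logged and recorded as their partial
    trajectories rather than aborting the whole portrait.
    """
    trajectories = []
    for init in grid:
        try:
            trajectories.append(integrate(params, SystemState(*init), t_max=t_max))
        except IntegrationError as exc:
            logger.error("trajectory from %s failed: %s", init, exc)
            if exc.partial is not None:
                trajectories.append(exc.partial)
    return trajectories


def sweep_phase_diagram(
    template: ModelParams,
    r_values: Sequence[float],
    p_beta_values: Sequence[float],
    verify_fraction: float = 0.0,
    seed: int = 0,
) -> PhaseDiagram:
    """Label an (r, p*beta) grid by the analytic regime classification.

    ``beta`` is held at the template value and ``p`` set to ``p_beta/beta``
    for each cell (permissively, so sweeps may probe p at or beyond the unit
    interval).  A random ``verify_fraction`` of the non-boundary cells is
    cross-checked by integrating from an interior initial condition; any
    mismatch raises :class:`ConsistencyError` naming the offending cell.
    Cells are independent, so the result does not depend on evaluation order.
    """
    if not (0.0 <= verify_fraction <= 1.0):
        raise ValueError("verify_fraction must lie in [0, 1]")
    r_grid = np.asarray(sorted(r_values), dtype=float)
    pb_grid = np.asarray(sorted(p_beta_values), dtype=float)
    if np.any(r_grid <= 0) or np.any(pb_grid <= 0):
        raise ValueError("r and p*beta grids must be strictly positive")

    labels: list[list[RegimeLabel]] = []
    verifiable: list[tuple[int, int]] = []
    for i, r in enumerate(r_grid):
        row = []
        for j, pb in enumerate(pb_grid):
            cell_params = template.with_(r=float(r), p=float(pb / template.beta), permissive=True)
            label = classify_regime(cell_params)
            row.append(label)
            if label.outcome is not Outcome.boundary_case:
                verifiable.append((i, j))
        labels.append(row)

    mask = np.zeros((len(r_grid), len(pb_grid)), dtype=bool)
    if verify_fraction > 0 and verifiable:
        rng = np.random.default_rng(seed)
        n_check = max(1, int(round(verify_fraction * len(verifiable))))
        chosen = rng.choice(len(verifiable), size=min(n_check, len(verifiable)), replace=False)
        for idx in chosen:
            i, j = verifiable[idx]
            cell_params = template.with_(
                r=float(r_grid[i]), p=float(pb_grid[j] / template.beta), permissive=True
            )
            start = SystemState(0.5, template.R_m / 2)
            terminal, matched = find_attractor(cell_params, start)
            predicted = labels[i][j].predicted_attractor
            ok = (
                matched is not None
                and predicted is not None
                and abs(matched.location.x - predicted.x) <= MATCH_TOL
                and abs(matched.location.y - predicted.y) / max(1.0, template.R_m) <= MATCH_TOL
            )
            if not ok:
                raise ConsistencyError(
                    f"cell (r={r_grid[i]:g}, p_beta={pb_grid[j]:g}): integration "
                    f"terminal {tuple(terminal)} disagrees with analytic attractor "
                    f"{None if predicted is None else tuple(predicted)}",
                    cell=(float(r_grid[i]), float(pb_grid[j])),
                )
            mask[i, j] = True
    return PhaseDiagram(
        r_grid=r_grid,
        p_beta_grid=pb_grid,
        labels=labels,
        verification_mask=mask,
        template=template,
    )


def _metadata_lines(params: ModelParams, extra: dict | None = None, timestamp: bool = True) -> list[str]:
    import datetime

    lines = [f"# commonsgame version {__version__}"]
    if timestamp:
        lines.append(f"# written {datetime.datetime.now().isoformat()}")
    for key, value in params.to_dict().items():
        lines.append(f"# param {key} = {value!r}")
    for key, value in (extra or {}).items():
        lines.append(f"# {key} = {value!r}")
    return lines


def trajectory_to_csv(traj: Trajectory, path, timestamp: bool = True) -> None:
    """Write a trajectory as CSV with '#'-prefixed metadata lines."""
    with open(path, "w") as fh:
        for line in _metadata_lines(traj.params, {"converged": traj.converged}, timestamp):
            fh.write(line + "\n")
        fh.write("t,x,y,y_over_Rm\n")
        for t, (x, y) in zip(traj.times, traj.states):
            fh.write(f"{float(t)!r},{float(x)!r},{float(y)!r},{float(y) / traj.params.R_m!r}\n")


def phase_diagram_to_csv(diagram: PhaseDiagram, path, timestamp: bool = True) -> None:
    """Write a phase diagram as long-format CSV (r, p_beta, outcome)."""
    with open(path, "w") as fh:
        for line in _metadata_lines(diagram.template, timestamp=timestamp):
            fh.write(line + "\n")
        fh.write("r,p_beta,growth_class,outcome,verified\n")
        for i, r in enumerate(diagram.r_grid):
            for j, pb in enumerate(diagram.p_beta_grid):
                label = diagram.labels[i][j]
                fh.write(
                    f"{float(r)!r},{float(pb)!r},{label.growth_class.value},"
                    f"{label.outcome.value},{bool(diagram.verification_mask[i, j])}\n"
                )
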