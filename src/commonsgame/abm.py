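"""Individual-based Monte Carlo counterpart of the mean-field model.

N agents each carry a binary strategy (1 = law-abiding/cooperator,
0 = violator/defector).  Per discrete time step:

1. payoffs are realized at the current resource level — cooperators collect
   the legal share ``y b_m / R_m`` deterministically, each defector collects
   ``(1+alpha) y b_m / R_m`` and is independently detected with probability
   ``p``, in which case the fine ``beta`` is subtracted;
2. the resource is updated with the *pre-imitation* strategies:
   ``y(t+1) = y + r y (1 - y/R_m) - sum_i [s_i y b_m/R_m +
   (1-s_i) y b_m (1+alpha)/R_m]``, floored at zero (extinction is absorbing);
3. every agent picks one uniform-random partner and, if the partner's frozen
   step payoff is higher, imitates the partner's strategy with probability
   ``q = (P_j - P_i)/M``; adoptions are committed synchronously.

``M`` normalizes ``q`` into [0, 1] as the largest payoff gap realizable at
the current resource level: the best-off agent is an undetected defector,
the worst-off is either a cooperator (gap ``alpha y b_m/R_m``) or a detected
defector (gap ``beta``), so ``M = max(alpha y b_m/R_m, beta)``.  A
resource-independent alternative ``M = max(alpha b_m, beta)`` is available
for sensitivity checks.

A single seeded generator drives each step in a fixed draw order — one
detection uniform per agent, one partner index per agent, one adoption
uniform per agent — so runs are bit-reproducible.  Once the strategy vector
is monomorphic it can never change (imitation only copies existing
strategies), so the simulation stops drawing random numbers and only the
resource keeps updating.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

from . import __version__
from .model_core import ModelParams

__all__ = [
    "AgentPopulation",
    "ABMConfig",
    "ABMRecord",
    "EnsembleSummary",
    "init_population",
    "realized_payoffs",
    "update_resource",
    "imitation_step",
    "run_abm",
    "ensemble_summary",
    "record_to_csv",
    "summary_to_json",
]

M_RULES = ("instantaneous", "static")


@dataclass
class AgentPopulation:
    """Binary strategy vector: 1 = cooperator (law-abiding), 0 = defector."""

    strategies: np.ndarray

    def __post_init__(self) -> None:
        self.strategies = np.asarray(self.strategies, dtype=np.int8)
        if self.strategies.ndim != 1:
            raise ValueError("strategies must be a 1-D sequence")
        if not np.all((self.strategies == 0) | (self.strategies == 1)):
            raise ValueError("strategies must contain only 0 (violator) and 1 (law-abiding)")

    @property
    def n(self) -> int:
        return self.strategies.size

    @property
    def coop_fraction(self) -> float:
        return float(self.strategies.mean())

    @property
    def is_monomorphic(self) -> bool:
        return bool(np.all(self.strategies == self.strategies[0]))


@dataclass(frozen=True)
class ABMConfig:
    """Run configuration for a single Monte Carlo realization."""

    x0: float
    y0: float
    t_max: int = 5000
    seed: int = 0
    record_every: int = 1
    m_rule: str = "instantaneous"

    def __post_init__(self) -> None:
        if not (0.0 <= self.x0 <= 1.0):
            raise ValueError(f"x0 must lie in [0, 1], got {self.x0!r}")
        if self.y0 < 0:
            raise ValueError(f"y0 must be non-negative, got {self.y0!r}")
        if self.t_max < 0:
            raise ValueError(f"t_max must be >= 0, got {self.t_max!r}")
        if self.record_every < 1:
            raise ValueError(f"record_every must be >= 1, got {self.record_every!r}")
        if self.m_rule not in M_RULES:
            raise ValueError(f"m_rule must be one of {M_RULES}, got {self.m_rule!r}")


@dataclass
class ABMRecord:
    """Sampled population state of one seeded run."""

    steps: np.ndarray
    coop_fraction: np.ndarray
    resource: np.ndarray
    absorbed_at: int | None
    params: ModelParams
    config: ABMConfig


@dataclass(frozen=True)
class EnsembleSummary:
    """Terminal-state mean and dispersion over independently seeded runs."""

    mean_coop: float
    mean_resource_ratio: float
    std_coop: float
    std_resource_ratio: float
    n_runs: int
    seeds: tuple[int, ...]


def init_population(params: ModelParams, x0: float, seed: int) -> AgentPopulation:
    """Exactly ``round(N * x0)`` cooperators at seeded-uniform shuffled positions.

    The exact count (rather than Bernoulli draws) removes initial-condition
    variance between runs.
    """
    if not (0.0 <= x0 <= 1.0):
        raise ValueError(f"x0 must lie in [0, 1], got {x0!r}")
    n_coop = int(round(params.N * x0))
    strategies = np.zeros(params.N, dtype=np.int8)
    strategies[:n_coop] = 1
    rng = np.random.default_rng(seed)
    rng.shuffle(strategies)
    return AgentPopulation(strategies)


def realized_payoffs(
    params: ModelParams,
    pop: AgentPopulation,
    y: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-agent payoffs with stochastic inspection at resource level ``y``.

    Consumes one uniform draw per agent (agent index order); the draw is only
    meaningful for defectors, who are detected when it falls below ``p``.
    """
    if y < 0:
        raise ValueError(f"resource amount y must be non-negative, got {y!r}")
    share = y * params.b_m / params.R_m
    s = pop.strategies
    detected = rng.random(pop.n) < params.p
    pay = np.where(
        s == 1,
        share,
        share * (1.0 + params.alpha) - np.where(detected, params.beta, 0.0),
    )
    return pay


def update_resource(params: ModelParams, pop: AgentPopulation, y: float) -> float:
    """Discrete-time resource update with the current strategies.

    Logistic regrowth minus the sum of individual harvests; floored at zero,
    and zero is absorbing.  Equivalent to
    ``y * (1 + r(1 - y/R_m) - e_c (1 + (1 - xbar) alpha))`` with
    ``xbar`` the cooperator fraction.
    """
    if y < 0:
        raise ValueError(f"resource amount y must be non-negative, got {y!r}")
    s = pop.strategies.astype(float)
    harvest_per_unit = s * params.b_m / params.R_m + (1.0 - s) * params.b_m * (
        1.0 + params.alpha
    ) / params.R_m
    y_next = y + params.r * y * (1.0 - y / params.R_m) - y * float(harvest_per_unit.sum())
    return max(0.0, y_next)


def _normalization(params: ModelParams, y: float, m_rule: str) -> float:
    if m_rule == "instantaneous":
        return max(params.alpha * y * params.b_m / params.R_m, params.beta)
    return max(params.alpha * params.b_m, params.beta)


def imitation_step(
    params: ModelParams,
    pop: AgentPopulation,
    payoffs: np.ndarray,
    y: float,
    rng: np.random.Generator,
    m_rule: str = "instantaneous",
) -> AgentPopulation:
    """Synchronous pairwise imitation against frozen payoffs.

    Each agent draws one uniform partner (excluding itself) and one adoption
    uniform; a strictly better-paid partner is imitated with probability
    ``q = (P_j - P_i)/M``, which the normalization keeps in [0, 1].  All
    adoptions read the input strategies and commit simultaneously.
    """
    n = pop.n
    if n < 2:
        return AgentPopulation(pop.strategies.copy())
    payoffs = np.asarray(payoffs, dtype=float)
    # partner j != i: draw in [0, n-1) then shift past self
    raw = rng.integers(0, n - 1, size=n)
    partners = raw + (raw >= np.arange(n))
    u_adopt = rng.random(n)
    m = _normalization(params, y, m_rule)
    gap = payoffs[partners] - payoffs
    if m > 0:
        q = np.clip(gap / m, 0.0, None)
    else:  # only reachable with permissive beta=0 at y=0: no payoff spread
        q = np.zeros(n)
    adopt = (gap > 0) & (u_adopt < q)
    new_strategies = np.where(adopt, pop.strategies[partners], pop.strategies)
    return AgentPopulation(new_strategies.astype(np.int8))


def run_abm(params: ModelParams, config: ABMConfig) -> ABMRecord:
    """One seeded Monte Carlo realization.

    Per step: realize payoffs at ``y(t)``, compute ``y(t+1)`` from the step-t
    strategies, then imitate against the frozen step-t payoffs.  After the
    strategy vector becomes monomorphic only the resource keeps evolving (and
    no further random numbers are drawn), up to ``t_max`` steps.
    """
    # single generator for the whole run: initial shuffle, then per step
    # detections, partner choices, adoption coin-flips (agent index order)
    rng = np.random.default_rng(config.seed)
    n_coop = int(round(params.N * config.x0))
    strategies = np.zeros(params.N, dtype=np.int8)
    strategies[:n_coop] = 1
    rng.shuffle(strategies)
    pop = AgentPopulation(strategies)
    y = float(config.y0)

    steps, fractions, resources = [], [], []
    absorbed_at: int | None = 0 if pop.is_monomorphic else None

    def record(step: int) -> None:
        steps.append(step)
        fractions.append(pop.coop_fraction)
        resources.append(y)

    record(0)
    for t in range(config.t_max):
        if absorbed_at is None:
            pay = realized_payoffs(params, pop, y, rng)
            y_next = update_resource(params, pop, y)
            pop = imitation_step(params, pop, pay, y, rng, m_rule=config.m_rule)
            if pop.is_monomorphic:
                absorbed_at = t + 1
        else:
            y_next = update_resource(params, pop, y)
        y = y_next
        step = t + 1
        if step % config.record_every == 0 or step == config.t_max:
            record(step)

    return ABMRecord(
        steps=np.asarray(steps, dtype=int),
        coop_fraction=np.asarray(fractions, dtype=float),
        resource=np.asarray(resources, dtype=float),
        absorbed_at=absorbed_at,
        params=params,
        config=config,
    )


def ensemble_summary(
    params: ModelParams,
    config: ABMConfig,
    n_runs: int,
    base_seed: int,
) -> EnsembleSummary:
    """Terminal-state statistics over ``n_runs`` with consecutive seeds."""
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs!r}")
    seeds = tuple(range(base_seed, base_seed + n_runs))
    terminal_x, terminal_yr = [], []
    for seed in seeds:
        rec = run_abm(params, ABMConfig(
            x0=config.x0,
            y0=config.y0,
            t_max=config.t_max,
            seed=seed,
            record_every=config.record_every,
            m_rule=config.m_rule,
        ))
        terminal_x.append(rec.coop_fraction[-1])
        terminal_yr.append(rec.resource[-1] / params.R_m)
    tx = np.asarray(terminal_x)
    ty = np.asarray(terminal_yr)
    return EnsembleSummary(
        mean_coop=float(tx.mean()),
        mean_resource_ratio=float(ty.mean()),
        std_coop=float(tx.std()),
        std_resource_ratio=float(ty.std()),
        n_runs=n_runs,
        seeds=seeds,
    )


def record_to_csv(record: ABMRecord, path, timestamp: bool = True) -> None:
    """Write an ABM run as CSV with '#'-prefixed metadata lines."""
    import datetime

    with open(path, "w") as fh:
        fh.write(f"# commonsgame version {__version__}\n")
        if timestamp:
            fh.write(f"# written {datetime.datetime.now().isoformat()}\n")
        for key, value in record.params.to_dict().items():
            fh.write(f"# param {key} = {value!r}\n")
        fh.write(f"# seed = {record.config.seed}\n")
        fh.write(f"# x0 = {record.config.x0!r}\n")
        fh.write(f"# y0 = {record.config.y0!r}\n")
        fh.write(f"# absorbed_at = {record.absorbed_at}\n")
        fh.write("step,coop_fraction,resource,resource_over_Rm\n")
        for step, xbar, y in zip(record.steps, record.coop_fraction, record.resource):
            fh.write(f"{step},{float(xbar)!r},{float(y)!r},{float(y) / record.params.R_m!r}\n")


def summary_to_json(
    params: ModelParams, summary: EnsembleSummary, indent: int = 2
) -> str:
    doc = {
        "params": params.to_dict(),
        "n_runs": summary.n_runs,
        "seeds": list(summary.seeds),
        "terminal_mean": {
            "coop_fraction": summary.mean_coop,
            "resource_over_Rm": summary.mean_resource_ratio,
        },
        "terminal_std": {
            "coop_fraction": summary.std_coop,
            "resource_over_Rm": summary.std_resource_ratio,
        },
    }
    return json.dumps(doc, indent=indent)
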