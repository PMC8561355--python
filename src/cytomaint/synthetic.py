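"""Synthetic decision problems, repairable systems, and a CTMC simulator.

The generators emulate the two input kinds the analysis consumes, so every
pipeline stage is testable without external data:

* random decision problems whose judgements are drawn from the packaged
  seven-level linguistic scales, with a configurable fraction of
  adjacent-label interval judgements (the only interval form the scales'
  users employ in practice);
* random repairable systems whose section rates are drawn log-uniformly,
  failure rates a couple of orders of magnitude below repair rates by
  default (the repairable regime: faults per ~10^4 h, repairs per ~10^2 h).

``simulate_availability`` is an event-driven Monte-Carlo simulation of the
load-sharing birth–death chain (exponential holding times, the exact rates
the analytic chain uses) and serves as a stochastic oracle for the
steady-state availability solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fuzzy import Judgement, RATING_SCALE, WEIGHT_SCALE, LinguisticScale
from .markov import (
    RepairableSystem,
    SectionRates,
    build_chain,
    equivalent_rates,
)
from .topsis import Criterion, DecisionProblem, Direction

__all__ = [
    "ProblemGeneratorConfig",
    "SystemGeneratorConfig",
    "SimulationResult",
    "generate_problem",
    "generate_system",
    "simulate_availability",
]


@dataclass(frozen=True)
class ProblemGeneratorConfig:
    """Shape and randomness of a generated decision problem.

    Defaults mirror the cytostatic case study's shape: 4 alternatives rated
    on 6 criteria of which 2 are costs, by a single consensus group, with
    interval judgements used sparingly.
    """

    n_alternatives: int = 4
    n_criteria: int = 6
    n_cost_criteria: int = 2
    n_decision_makers: int = 1
    interval_judgement_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_alternatives", "n_criteria", "n_decision_makers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_cost_criteria <= self.n_criteria:
            raise ValueError("n_cost_criteria must be in [0, n_criteria]")
        if not 0.0 <= self.interval_judgement_prob <= 1.0:
            raise ValueError("interval_judgement_prob must be in [0, 1]")


@dataclass(frozen=True)
class SystemGeneratorConfig:
    """Shape and rate ranges of a generated repairable system (per-hour)."""

    n_sections: int = 3
    lambda_range: tuple[float, float] = (1e-5, 1e-3)
    mu_range: tuple[float, float] = (1e-2, 1e-1)
    n_units_max: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.n_units_max < 1:
            raise ValueError("n_units_max must be >= 1")
        for name in ("lambda_range", "mu_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")


def _draw_judgement(
    rng: np.random.Generator, scale: LinguisticScale, interval_prob: float
) -> Judgement:
    labels = scale.labels
    if rng.random() < interval_prob:
        i = int(rng.integers(0, len(labels) - 1))  # adjacent-label interval
        return Judgement.from_interval(labels[i], labels[i + 1])
    return Judgement.from_label(labels[int(rng.integers(0, len(labels)))])


def generate_problem(cfg: ProblemGeneratorConfig) -> DecisionProblem:
    """Random decision problem with scale-drawn judgements; seed-determined."""
    rng = np.random.default_rng(cfg.seed)
    criteria = tuple(
        Criterion(
            name=f"C{j + 1}",
            direction=Direction.COST if j < cfg.n_cost_criteria else Direction.BENEFIT,
        )
        for j in range(cfg.n_criteria)
    )
    alternatives = tuple(f"A{i + 1}" for i in range(cfg.n_alternatives))
    makers = tuple(f"DM{k + 1}" for k in range(cfg.n_decision_makers))
    p = cfg.interval_judgement_prob
    weight_judgements = {
        (dm, c.name): _draw_judgement(rng, WEIGHT_SCALE, p)
        for dm in makers
        for c in criteria
    }
    rating_judgements = {
        (dm, alt, c.name): _draw_judgement(rng, RATING_SCALE, p)
        for dm in makers
        for alt in alternatives
        for c in criteria
    }
    return DecisionProblem(
        criteria=criteria,
        alternatives=alternatives,
        decision_makers=makers,
        weight_judgements=weight_judgements,
        rating_judgements=rating_judgements,
    )


def generate_system(cfg: SystemGeneratorConfig) -> RepairableSystem:
    """Random repairable system; rates log-uniform in range; seed-determined."""
    rng = np.random.default_rng(cfg.seed)

    def log_uniform(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    sections = tuple(
        SectionRates(
            name=f"S{j + 1}",
            failure_rate=log_uniform(*cfg.lambda_range),
            repair_rate=log_uniform(*cfg.mu_range),
        )
        for j in range(cfg.n_sections)
    )
    n_units = int(rng.integers(1, cfg.n_units_max + 1))
    return RepairableSystem(sections=sections, n_units=n_units)


@dataclass(frozen=True)
class SimulationResult:
    """Monte-Carlo availability estimate: replicate mean and standard error."""

    mean: float
    se: float
    replicates: tuple[float, ...] = field(repr=False, default=())


def simulate_availability(
    system: RepairableSystem,
    horizon: float,
    n_reps: int,
    seed: int = 0,
    burn_in_fraction: float = 0.1,
) -> SimulationResult:
    """Estimate long-run availability by event-driven CTMC simulation.

    Simulates the load-sharing birth–death chain with the exact rates the
    analytic model uses: failure i -> i+1 at (n - i)λ_eq, repair at μ_eq,
    exponential holding times.  Each replicate reports the fraction of
    post-burn-in time spent in operational states; the estimate is the
    replicate mean with its standard error.  A system whose active sections
    never fail yields exactly 1.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must be in [0, 1)")

    if sum(s.failure_rate for s in system.active) == 0:
        return SimulationResult(mean=1.0, se=0.0, replicates=(1.0,) * n_reps)

    rates = equivalent_rates(system)
    model = build_chain(system.n_units, rates)
    lam, mu = rates.lambda_eq, rates.mu_eq
    n = system.n_units
    operational = model.operational_states
    burn_in = burn_in_fraction * horizon
    window = horizon - burn_in

    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        t = 0.0
        state = 0
        up_time = 0.0
        while t < horizon:
            fail = (n - state) * lam
            repair = mu if state > 0 else 0.0
            total = fail + repair
            dt = rng.exponential(1.0 / total)
            t_next = min(t + dt, horizon)
            if state in operational and t_next > burn_in:
                up_time += t_next - max(t, burn_in)
            if t + dt >= horizon:
                break
            state += 1 if rng.random() * total < fail else -1
            t += dt
        reps.append(up_time / window)

    arr = np.asarray(reps)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return SimulationResult(mean=mean, se=se, replicates=tuple(reps))
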