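"""Steady-state availability of redundant repairable systems via CTMCs.

A preparation hood is a series arrangement of sections (filter, gas
extraction, control/alarms), each with constant failure rate λ_j and repair
rate μ_j per hour (exponential failure and repair times).  The sections
collapse into a single equivalent failure rate λ = Σλ_j and equivalent repair
rate μ = λ / Σ(λ_j/μ_j), so a system of n identical hoods becomes a
birth–death chain on states 0..n (number of failed hoods).

Modelling conventions, matching the maintenance alternatives analysed:

* Load sharing (hot standby): every working hood carries an equal share of
  the workload, so the aggregate failure rate from state i is (n - i)·λ.
* One repair crew: every repair transition occurs at rate μ, not i·μ.
* The system is operational unless all hoods are down (states 0..n-1).
* Scheduled preventive windows are programmed work, not downtime, and are
  not represented in the chain.

The stationary distribution solves p·A = (0,...,0,1), where A is the
infinitesimal generator with its last column replaced by ones (the
normalisation Σp_i = 1 replacing one redundant balance equation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SectionRates",
    "RepairableSystem",
    "EquivalentRates",
    "MarkovModel",
    "AvailabilityResult",
    "equivalent_rates",
    "build_chain",
    "steady_state",
    "availability_single",
    "availability_series",
    "availability_transient",
    "system_availability",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class SectionRates:
    """Failure and repair rates (per hour) of one section of a hood."""

    name: str
    failure_rate: float
    repair_rate: float

    def __post_init__(self) -> None:
        if self.failure_rate < 0:
            raise ValueError(
                f"section {self.name!r}: failure_rate must be >= 0, "
                f"got {self.failure_rate}"
            )
        if self.repair_rate <= 0:
            raise ValueError(
                f"section {self.name!r}: repair_rate must be > 0, "
                f"got {self.repair_rate}"
            )


@dataclass(frozen=True)
class RepairableSystem:
    """A redundant system of identical multi-section units (hoods).

    ``active_sections`` selects the policy variant: sections not listed are
    removed from the failure pool (e.g. outsourced predictive maintenance on
    the filter section removes it).  Default: all sections active.
    """

    sections: tuple[SectionRates, ...]
    n_units: int = 1
    active_sections: frozenset[str] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError(f"n_units must be >= 1, got {self.n_units}")
        if not self.sections:
            raise ValueError("a system needs at least one section")
        names = {s.name for s in self.sections}
        if len(names) != len(self.sections):
            raise ValueError("section names must be unique")
        if self.active_sections is not None:
            if not self.active_sections:
                raise ValueError("active_sections must be nonempty")
            unknown = self.active_sections - names
            if unknown:
                raise ValueError(f"unknown active sections: {sorted(unknown)}")

    @property
    def active(self) -> tuple[SectionRates, ...]:
        if self.active_sections is None:
            return self.sections
        return tuple(s for s in self.sections if s.name in self.active_sections)

    def with_units(self, n_units: int) -> "RepairableSystem":
        return RepairableSystem(
            self.sections, n_units, self.active_sections, self.name
        )


@dataclass(frozen=True)
class EquivalentRates:
    """Collapsed series-system failure and repair rates (per hour)."""

    lambda_eq: float
    mu_eq: float

    def __post_init__(self) -> None:
        if self.lambda_eq < 0:
            raise ValueError(f"lambda_eq must be >= 0, got {self.lambda_eq}")
        if self.mu_eq <= 0:
            raise ValueError(f"mu_eq must be > 0, got {self.mu_eq}")


def equivalent_rates(system: RepairableSystem | Iterable[SectionRates]) -> EquivalentRates:
    """Equivalent rates of the active sections in series.

    λ_eq = Σ λ_j;  μ_eq = λ_eq / Σ(λ_j / μ_j).  The repair rate is the
    failure-frequency-weighted harmonic combination that preserves the series
    unavailability λ_eq/μ_eq = Σ λ_j/μ_j.
    """
    sections = system.active if isinstance(system, RepairableSystem) else tuple(system)
    lam = sum(s.failure_rate for s in sections)
    downtime = sum(s.failure_rate / s.repair_rate for s in sections)
    if downtime == 0:
        raise ValueError(
            "equivalent repair rate undefined: all active sections have "
            "zero failure rate"
        )
    return EquivalentRates(lambda_eq=lam, mu_eq=lam / downtime)


@dataclass(frozen=True)
class MarkovModel:
    """A finite CTMC given by its off-diagonal transition rates.

    ``rates`` maps (i, j) with i != j to the transition rate; the generator's
    diagonal is minus the row sums.  ``operational_states`` flags the states
    in which the system delivers service.
    """

    n_states: int
    rates: Mapping[tuple[int, int], float]
    operational_states: frozenset[int]

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        for (i, j), r in self.rates.items():
            if i == j:
                raise ValueError("rates maps off-diagonal transitions only")
            if not (0 <= i < self.n_states and 0 <= j < self.n_states):
                raise ValueError(f"transition ({i}, {j}) out of range")
            if r < 0:
                raise ValueError(f"negative rate {r} on transition ({i}, {j})")
        if not self.operational_states:
            raise ValueError("operational_states must be nonempty")
        if not set(self.operational_states) <= set(range(self.n_states)):
            raise ValueError("operational_states out of range")

    def generator(self) -> np.ndarray:
        """Infinitesimal generator Q (rows sum to zero)."""
        q = np.zeros((self.n_states, self.n_states))
        for (i, j), r in self.rates.items():
            q[i, j] = r
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def solve_matrix(self) -> np.ndarray:
        """Generator with the last column replaced by ones (normalisation)."""
        a = self.generator()
        a[:, -1] = 1.0
        return a


@dataclass(frozen=True)
class AvailabilityResult:
    """Stationary distribution and the mean availability D_m it implies."""

    steady_state: tuple[float, ...]
    mean_availability: float

    def rounded(self, ndigits: int = 4) -> float:
        """Mean availability at the reporting precision (default 4 d.p.)."""
        return round(self.mean_availability, ndigits)


def build_chain(n_units: int, rates: EquivalentRates) -> MarkovModel:
    """Birth–death availability chain for n load-sharing units, one repair crew.

    States count failed units.  Failure i -> i+1 at (n - i)·λ; repair
    i -> i-1 at μ.  Operational in every state but the last (all units down).
    """
    if n_units < 1:
        raise ValueError(f"n_units must be >= 1, got {n_units}")
    lam, mu = rates.lambda_eq, rates.mu_eq
    chain: dict[tuple[int, int], float] = {}
    for i in range(n_units):
        chain[(i, i + 1)] = (n_units - i) * lam
        chain[(i + 1, i)] = mu
    return MarkovModel(
        n_states=n_units + 1,
        rates=chain,
        operational_states=frozenset(range(n_units)),
    )


def steady_state(model: MarkovModel) -> AvailabilityResult:
    """Solve p·A = (0,...,0,1) and sum p over the operational states."""
    a = model.solve_matrix()
    b = np.zeros(model.n_states)
    b[-1] = 1.0
    try:
        p = np.linalg.solve(a.T, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular solve matrix: {exc}") from exc
    total = p.sum()
    if abs(total - 1.0) > _PROB_TOL or (p < -_PROB_TOL).any():
        raise ValueError(
            f"invalid stationary distribution (sum={total!r}, min={p.min()!r}); "
            "is the chain irreducible?"
        )
    p = np.clip(p, 0.0, None)
    dm = float(p[sorted(model.operational_states)].sum())
    return AvailabilityResult(steady_state=tuple(float(x) for x in p), mean_availability=dm)


def availability_single(rates: EquivalentRates) -> float:
    """Asymptotic availability of one unit: μ / (λ + μ)."""
    return rates.mu_eq / (rates.lambda_eq + rates.mu_eq)


def availability_series(sections: Sequence[SectionRates]) -> float:
    """Closed form for one multi-section unit: 1 / (1 + Σ λ_j/μ_j).

    Algebraically identical to ``availability_single(equivalent_rates(...))``.
    """
    return 1.0 / (1.0 + sum(s.failure_rate / s.repair_rate for s in sections))


def availability_transient(t: float, rates: EquivalentRates) -> float:
    """Two-state point availability D(t) = μ/(λ+μ) + λ/(λ+μ)·exp(-(λ+μ)t).

    Starts at 1 (unit initially up) and decays to the asymptote μ/(λ+μ).
    """
    lam, mu = rates.lambda_eq, rates.mu_eq
    s = lam + mu
    return mu / s + lam / s * math.exp(-s * t)


def system_availability(system: RepairableSystem) -> AvailabilityResult:
    """Full pipeline for one system: equivalent rates -> chain -> steady state."""
    rates = equivalent_rates(system)
    return steady_state(build_chain(system.n_units, rates))
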