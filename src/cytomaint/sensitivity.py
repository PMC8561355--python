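"""Criteria-weight sensitivity analysis for the fuzzy TOPSIS ranking.

Each scenario scales one criterion's aggregated fuzzy weight componentwise by
(1 + delta) for delta in {-20%, -10%, +10%, +20%}, clips the components back
to [0, 1] (the weight scale's range), reruns the whole pipeline with the
other weights untouched, and records the resulting closeness coefficients and
ranking.  Weights are perturbed directly — fuzzy TOPSIS imposes no
sum-to-one constraint, so no renormalisation of the remaining weights is
applied.  The model is called robust (``stable``) when every scenario
reproduces the baseline ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .fuzzy import TFN
from .topsis import DecisionProblem, PipelineOutput, TopsisResult, run_pipeline

__all__ = ["DEFAULT_DELTAS", "Scenario", "SensitivityReport", "perturb_weight",
           "perturb_and_rank", "full_report"]

logger = logging.getLogger(__name__)

DEFAULT_DELTAS: tuple[float, ...] = (-0.20, -0.10, 0.10, 0.20)


def perturb_weight(weight: TFN, delta: float) -> TFN:
    """Scale a fuzzy weight componentwise by (1 + delta), clipped to [0, 1]."""
    if delta <= -1:
        raise ValueError(f"delta must be > -1, got {delta}")
    factor = 1.0 + delta
    raw = (factor * weight.l, factor * weight.m, factor * weight.u)
    clipped = tuple(min(max(x, 0.0), 1.0) for x in raw)
    if clipped != raw:
        logger.info(
            "perturbed weight clipped to the [0, 1] scale range: %s -> %s",
            raw,
            clipped,
        )
    return TFN(*clipped)


@dataclass(frozen=True)
class Scenario:
    """One perturbation: a criterion, a signed delta, and the outcome."""

    criterion: str
    delta: float
    cc: Mapping[str, float]
    ranking: tuple[str, ...]


@dataclass(frozen=True)
class SensitivityReport:
    """All scenarios plus the baseline; stable iff no ranking changed."""

    baseline: TopsisResult
    scenarios: tuple[Scenario, ...]
    stable: bool

    def to_frame(self, ndigits: int = 3) -> pd.DataFrame:
        rows = []
        for s in self.scenarios:
            row: dict = {"criterion": s.criterion, "delta": s.delta}
            row.update({alt: round(s.cc[alt], ndigits) for alt in s.cc})
            row["ranking"] = " > ".join(s.ranking)
            rows.append(row)
        return pd.DataFrame(rows)


def perturb_and_rank(
    problem: DecisionProblem,
    criterion: str,
    delta: float,
    *,
    baseline: PipelineOutput | None = None,
    **pipeline_options,
) -> TopsisResult:
    """Rerun the pipeline with one criterion's aggregated weight perturbed."""
    if baseline is None:
        baseline = run_pipeline(problem, **pipeline_options)
    if criterion not in baseline.weights:
        raise KeyError(f"unknown criterion {criterion!r}")
    weights = dict(baseline.weights)
    weights[criterion] = perturb_weight(weights[criterion], delta)
    out = run_pipeline(problem, weights_override=weights, **pipeline_options)
    return out.result


def full_report(
    problem: DecisionProblem,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    **pipeline_options,
) -> SensitivityReport:
    """Perturb every criterion by every delta; flag ranking stability."""
    baseline = run_pipeline(problem, **pipeline_options)
    scenarios = []
    stable = True
    for crit in problem.criterion_names:
        for delta in deltas:
            result = perturb_and_rank(
                problem, crit, delta, baseline=baseline, **pipeline_options
            )
            if result.ranking != baseline.result.ranking:
                stable = False
                logger.info(
                    "ranking changed for criterion %s, delta %+g%%: %s",
                    crit,
                    100 * delta,
                    result.ranking,
                )
            scenarios.append(
                Scenario(
                    criterion=crit,
                    delta=delta,
                    cc=result.cc,
                    ranking=result.ranking,
                )
            )
    return SensitivityReport(
        baseline=baseline.result, scenarios=tuple(scenarios), stable=stable
    )
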