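"""Fuzzy TOPSIS group decision pipeline on triangular fuzzy judgements.

Given criteria (each a benefit or a cost), alternatives, and per-decision-maker
linguistic judgements for criterion weights and alternative ratings, the
pipeline

1. resolves judgements to TFNs and aggregates over the K decision makers by
   the componentwise mean,
2. normalises the decision matrix onto [0, 1],
3. multiplies each column by its fuzzy weight,
4. measures each alternative's summed vertex distance d+ and d- to the fuzzy
   positive and negative ideal solutions (FPIS / FNIS), and
5. ranks by the closeness coefficient CC = d- / (d- + d+), decreasing.

Two conventions are selectable.  The default pair — GLOBAL_MAX normalisation
(divide every column by its largest upper bound) with ABSOLUTE ideals (fixed
crisp profiles (1,1,1)/(0,0,0), direction-swapped for cost criteria) — defers
all cost/benefit handling to the ideal profiles and keeps the ideals
data-independent, the construction recommended against rank reversal.  When
full rank-reversal resistance is wanted even against alternatives that raise
a column maximum, SCALE_MAX normalisation fixes the denominator at the
rating scale's upper bound instead.  The COST_INVERSE normalisation variant
inverts cost columns through the smallest lower bound, and CHEN ideals are
the classical per-column extremes of the weighted matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .fuzzy import (
    TFN,
    CombineRule,
    Judgement,
    LinguisticScale,
    RATING_SCALE,
    WEIGHT_SCALE,
    resolve_judgement,
    tfn_add,
    tfn_mul,
    tfn_scale,
    vertex_distance,
)

__all__ = [
    "Direction",
    "Criterion",
    "DecisionProblem",
    "FuzzyMatrix",
    "ReferenceSolutions",
    "TopsisResult",
    "NormalisationMode",
    "IdealConvention",
    "aggregate_weights",
    "aggregate_ratings",
    "normalise",
    "apply_weights",
    "reference_solutions",
    "separations",
    "closeness",
    "run_pipeline",
    "PipelineOutput",
]

logger = logging.getLogger(__name__)


class Direction(Enum):
    BENEFIT = "benefit"
    COST = "cost"


class NormalisationMode(Enum):
    GLOBAL_MAX = "global_max"
    COST_INVERSE = "cost_inverse"
    SCALE_MAX = "scale_max"


class IdealConvention(Enum):
    ABSOLUTE = "absolute"
    CHEN = "chen"


@dataclass(frozen=True)
class Criterion:
    """A decision criterion with an explicit optimisation direction.

    ``descriptor`` holds the agreed operational description of the criterion's
    performance levels; it is documentation only and never enters the numbers.
    """

    name: str
    direction: Direction
    descriptor: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.direction, Direction):
            raise TypeError(
                f"criterion {self.name!r}: direction must be a Direction, "
                f"got {self.direction!r}"
            )


@dataclass(frozen=True)
class DecisionProblem:
    """A fuzzy group decision problem: who judges what, on which scales.

    ``weight_judgements`` maps (decision_maker, criterion_name) to a
    Judgement; ``rating_judgements`` maps (decision_maker, alternative,
    criterion_name).  Every cell must be populated.
    """

    criteria: tuple[Criterion, ...]
    alternatives: tuple[str, ...]
    decision_makers: tuple[str, ...]
    weight_judgements: Mapping[tuple[str, str], Judgement]
    rating_judgements: Mapping[tuple[str, str, str], Judgement]

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValueError("at least one criterion is required")
        if not self.alternatives:
            raise ValueError("at least one alternative is required")
        if not self.decision_makers:
            raise ValueError("at least one decision maker is required")
        if len({c.name for c in self.criteria}) != len(self.criteria):
            raise ValueError("criterion names must be unique")
        if len(set(self.alternatives)) != len(self.alternatives):
            raise ValueError("alternative names must be unique")
        for dm in self.decision_makers:
            for c in self.criteria:
                if (dm, c.name) not in self.weight_judgements:
                    raise ValueError(
                        f"missing weight judgement for maker {dm!r}, "
                        f"criterion {c.name!r}"
                    )
                for alt in self.alternatives:
                    if (dm, alt, c.name) not in self.rating_judgements:
                        raise ValueError(
                            f"missing rating judgement for maker {dm!r}, "
                            f"alternative {alt!r}, criterion {c.name!r}"
                        )

    @property
    def criterion_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.criteria)

    def criterion(self, name: str) -> Criterion:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(f"unknown criterion {name!r}")


@dataclass(frozen=True)
class FuzzyMatrix:
    """Per-(alternative, criterion) TFN entries at one pipeline stage."""

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    entries: Mapping[tuple[str, str], TFN]
    stage: str

    def __post_init__(self) -> None:
        for alt in self.alternatives:
            for crit in self.criteria:
                if (alt, crit) not in self.entries:
                    raise ValueError(f"missing entry ({alt!r}, {crit!r})")

    def __getitem__(self, key: tuple[str, str]) -> TFN:
        return self.entries[key]

    def to_frame(self, ndigits: int | None = 3) -> pd.DataFrame:
        """Tabular view with '(l, m, u)' strings, rows = alternatives."""

        def fmt(t: TFN) -> str:
            if ndigits is None:
                return f"({t.l:g}, {t.m:g}, {t.u:g})"
            return f"({t.l:.{ndigits}f}, {t.m:.{ndigits}f}, {t.u:.{ndigits}f})"

        return pd.DataFrame(
            {c: [fmt(self.entries[(a, c)]) for a in self.alternatives] for c in self.criteria},
            index=list(self.alternatives),
        )


@dataclass(frozen=True)
class ReferenceSolutions:
    """Per-criterion fuzzy positive and negative ideal profiles."""

    fpis: Mapping[str, TFN]
    fnis: Mapping[str, TFN]


@dataclass(frozen=True)
class TopsisResult:
    """Separations, closeness coefficients and the resulting ranking."""

    d_plus: Mapping[str, float]
    d_minus: Mapping[str, float]
    cc: Mapping[str, float]
    ranking: tuple[str, ...]

    def rank_of(self, alternative: str) -> int:
        """1-based rank of an alternative."""
        return self.ranking.index(alternative) + 1

    def to_frame(self, ndigits: int = 3) -> pd.DataFrame:
        rows = {
            alt: {
                "d_plus": round(self.d_plus[alt], ndigits),
                "d_minus": round(self.d_minus[alt], ndigits),
                "cc": round(self.cc[alt], ndigits),
                "rank": self.rank_of(alt),
            }
            for alt in self.d_plus
        }
        return pd.DataFrame.from_dict(rows, orient="index")


def _aggregate(tfns: Sequence[TFN]) -> TFN:
    """Componentwise mean over decision makers."""
    total = tfns[0]
    for t in tfns[1:]:
        total = tfn_add(total, t)
    return tfn_scale(1.0 / len(tfns), total)


def aggregate_weights(
    problem: DecisionProblem,
    scale: LinguisticScale = WEIGHT_SCALE,
    combine_rule: CombineRule = CombineRule.MEAN_OF_MODALS,
) -> dict[str, TFN]:
    """Group fuzzy weight per criterion: mean of the K makers' resolved TFNs."""
    return {
        c.name: _aggregate(
            [
                resolve_judgement(
                    problem.weight_judgements[(dm, c.name)], scale, combine_rule
                )
                for dm in problem.decision_makers
            ]
        )
        for c in problem.criteria
    }


def aggregate_ratings(
    problem: DecisionProblem,
    scale: LinguisticScale = RATING_SCALE,
    combine_rule: CombineRule = CombineRule.MEAN_OF_MODALS,
) -> FuzzyMatrix:
    """Group fuzzy rating per (alternative, criterion)."""
    entries = {
        (alt, c.name): _aggregate(
            [
                resolve_judgement(
                    problem.rating_judgements[(dm, alt, c.name)], scale, combine_rule
                )
                for dm in problem.decision_makers
            ]
        )
        for alt in problem.alternatives
        for c in problem.criteria
    }
    return FuzzyMatrix(
        alternatives=problem.alternatives,
        criteria=problem.criterion_names,
        entries=entries,
        stage="aggregated",
    )


def normalise(
    matrix: FuzzyMatrix,
    criteria: Sequence[Criterion],
    mode: NormalisationMode = NormalisationMode.GLOBAL_MAX,
    scale_max: float | None = None,
) -> FuzzyMatrix:
    """Linear scale transformation of the aggregated matrix onto [0, 1].

    GLOBAL_MAX divides every column — benefit and cost alike — by the
    column's largest upper bound u+_j, leaving cost direction to the ideal
    profiles.  SCALE_MAX divides every entry by the fixed ``scale_max``
    (the rating scale's upper bound): the fictional-alternative construction
    whose denominator never depends on which alternatives are present, so
    adding or removing alternatives cannot reverse existing ranks.
    COST_INVERSE treats benefit columns as GLOBAL_MAX but maps cost entries to
    (l-_j/u_ij, l-_j/m_ij, l-_j/l_ij) with l-_j the column's smallest lower
    bound, so smaller raw cost becomes larger normalised score; it rejects
    cost entries with any zero component.
    """
    if matrix.stage != "aggregated":
        raise ValueError(f"expected an aggregated matrix, got stage {matrix.stage!r}")
    if mode is NormalisationMode.SCALE_MAX and not (scale_max and scale_max > 0):
        raise ValueError("SCALE_MAX normalisation needs a positive scale_max")
    by_name = {c.name: c for c in criteria}
    entries: dict[tuple[str, str], TFN] = {}
    for crit in matrix.criteria:
        col = [matrix[(alt, crit)] for alt in matrix.alternatives]
        direction = by_name[crit].direction
        if mode is not NormalisationMode.COST_INVERSE or direction is Direction.BENEFIT:
            if mode is NormalisationMode.SCALE_MAX:
                u_plus = float(scale_max)  # type: ignore[arg-type]
            else:
                u_plus = max(t.u for t in col)
            if u_plus == 0:
                raise ValueError(f"criterion {crit!r}: all upper bounds are zero")
            for alt, t in zip(matrix.alternatives, col):
                entries[(alt, crit)] = TFN(t.l / u_plus, t.m / u_plus, t.u / u_plus)
        else:  # COST_INVERSE on a cost column
            l_minus = min(t.l for t in col)
            for alt, t in zip(matrix.alternatives, col):
                if min(t.l, t.m, t.u) <= 0:
                    raise ValueError(
                        f"cost criterion {crit!r}, alternative {alt!r}: "
                        "COST_INVERSE normalisation needs strictly positive "
                        f"components, got {t}"
                    )
                entries[(alt, crit)] = TFN(l_minus / t.u, l_minus / t.m, l_minus / t.l)
    return FuzzyMatrix(matrix.alternatives, matrix.criteria, entries, stage="normalised")


def apply_weights(norm: FuzzyMatrix, weights: Mapping[str, TFN]) -> FuzzyMatrix:
    """Weighted matrix: v_ij = r_ij ⊗ w_j, componentwise."""
    if norm.stage != "normalised":
        raise ValueError(f"expected a normalised matrix, got stage {norm.stage!r}")
    entries = {
        (alt, crit): tfn_mul(norm[(alt, crit)], weights[crit])
        for alt in norm.alternatives
        for crit in norm.criteria
    }
    return FuzzyMatrix(norm.alternatives, norm.criteria, entries, stage="weighted")


_ONE = TFN(1.0, 1.0, 1.0)
_ZERO = TFN(0.0, 0.0, 0.0)


def reference_solutions(
    criteria: Sequence[Criterion],
    convention: IdealConvention = IdealConvention.ABSOLUTE,
    weighted: FuzzyMatrix | None = None,
) -> ReferenceSolutions:
    """FPIS/FNIS profiles.

    ABSOLUTE: fixed crisp references — benefit criteria aim at (1,1,1) and
    away from (0,0,0), cost criteria the reverse; independent of the data, so
    adding alternatives cannot move the ideals.  CHEN: classical data-driven
    crisp references from the weighted matrix's per-column extremes (max u
    for FPIS, min l for FNIS), provided for comparison.
    """
    if convention is IdealConvention.ABSOLUTE:
        fpis = {
            c.name: _ONE if c.direction is Direction.BENEFIT else _ZERO
            for c in criteria
        }
        fnis = {
            c.name: _ZERO if c.direction is Direction.BENEFIT else _ONE
            for c in criteria
        }
        return ReferenceSolutions(fpis=fpis, fnis=fnis)
    if weighted is None:
        raise ValueError("CHEN convention needs the weighted matrix")
    fpis, fnis = {}, {}
    for c in criteria:
        col = [weighted[(alt, c.name)] for alt in weighted.alternatives]
        hi = max(t.u for t in col)
        lo = min(t.l for t in col)
        fpis[c.name] = TFN(hi, hi, hi)
        fnis[c.name] = TFN(lo, lo, lo)
    return ReferenceSolutions(fpis=fpis, fnis=fnis)


def separations(
    weighted: FuzzyMatrix, refs: ReferenceSolutions
) -> tuple[dict[str, float], dict[str, float]]:
    """Summed vertex distances of each alternative to FPIS and FNIS."""
    if weighted.stage != "weighted":
        raise ValueError(f"expected a weighted matrix, got stage {weighted.stage!r}")
    d_plus = {
        alt: sum(
            vertex_distance(weighted[(alt, c)], refs.fpis[c]) for c in weighted.criteria
        )
        for alt in weighted.alternatives
    }
    d_minus = {
        alt: sum(
            vertex_distance(weighted[(alt, c)], refs.fnis[c]) for c in weighted.criteria
        )
        for alt in weighted.alternatives
    }
    return d_plus, d_minus


def closeness(
    d_plus: Mapping[str, float], d_minus: Mapping[str, float]
) -> TopsisResult:
    """Closeness coefficients CC = d-/(d- + d+) and the decreasing-CC ranking.

    Ties are broken lexicographically by alternative name (and logged).
    """
    cc: dict[str, float] = {}
    for alt in d_plus:
        denom = d_plus[alt] + d_minus[alt]
        if denom == 0:
            raise ValueError(
                f"alternative {alt!r}: d+ + d- = 0 (degenerate single-point "
                "problem); closeness undefined"
            )
        cc[alt] = d_minus[alt] / denom
    ranking = tuple(sorted(cc, key=lambda a: (-cc[a], a)))
    seen = sorted(cc.values())
    if len(set(seen)) != len(seen):
        logger.info("closeness ties present; broken lexicographically by name")
    return TopsisResult(d_plus=dict(d_plus), d_minus=dict(d_minus), cc=cc, ranking=ranking)


@dataclass(frozen=True)
class PipelineOutput:
    """All intermediate stages plus the final result of one TOPSIS run."""

    weights: Mapping[str, TFN]
    aggregated: FuzzyMatrix
    normalised: FuzzyMatrix
    weighted: FuzzyMatrix
    refs: ReferenceSolutions
    result: TopsisResult


def run_pipeline(
    problem: DecisionProblem,
    *,
    weight_scale: LinguisticScale = WEIGHT_SCALE,
    rating_scale: LinguisticScale = RATING_SCALE,
    combine_rule: CombineRule = CombineRule.MEAN_OF_MODALS,
    normalisation: NormalisationMode = NormalisationMode.GLOBAL_MAX,
    convention: IdealConvention = IdealConvention.ABSOLUTE,
    weights_override: Mapping[str, TFN] | None = None,
) -> PipelineOutput:
    """Run the full fuzzy TOPSIS pipeline deterministically.

    ``weights_override`` replaces the aggregated group weights (used by the
    weight-sensitivity analysis); all other stages are recomputed.
    """
    logger.info(
        "fuzzy TOPSIS: normalisation=%s, ideals=%s, combine_rule=%s",
        normalisation.value,
        convention.value,
        combine_rule.value,
    )
    weights = (
        dict(weights_override)
        if weights_override is not None
        else aggregate_weights(problem, weight_scale, combine_rule)
    )
    aggregated = aggregate_ratings(problem, rating_scale, combine_rule)
    normalised = normalise(
        aggregated, problem.criteria, normalisation, scale_max=rating_scale.max_u
    )
    weighted = apply_weights(normalised, weights)
    refs = reference_solutions(problem.criteria, convention, weighted=weighted)
    d_plus, d_minus = separations(weighted, refs)
    result = closeness(d_plus, d_minus)
    return PipelineOutput(
        weights=weights,
        aggregated=aggregated,
        normalised=normalised,
        weighted=weighted,
        refs=refs,
        result=result,
    )
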