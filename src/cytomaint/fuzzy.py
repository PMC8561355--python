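"""Triangular fuzzy number algebra and linguistic judgement scales.

A triangular fuzzy number (TFN) is an ordered triple ``(l, m, u)`` with
``l <= m <= u``: a fuzzy quantity whose membership rises linearly from 0 at
``l`` to 1 at the modal value ``m`` and falls back to 0 at ``u``.  TFNs carry
every judgement in the group-decision pipeline: linguistic labels such as
"Medium High" map to fixed TFNs on one of two seven-level scales (one for
criterion weights on [0, 1], one for alternative ratings on [0, 10]).

The arithmetic follows the standard componentwise operational laws.  Product
and quotient are the usual first-order approximations, exact at the vertices;
they are only guaranteed to yield a valid triangle for operands with
nonnegative support, and the constructors re-validate the ordering so a
mixed-sign misuse fails loudly rather than silently producing a non-triangle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Mapping, Union

__all__ = [
    "TriangularFuzzyNumber",
    "TFN",
    "tfn_add",
    "tfn_sub",
    "tfn_mul",
    "tfn_div",
    "tfn_inv",
    "tfn_scale",
    "membership",
    "vertex_distance",
    "CombineRule",
    "LinguisticScale",
    "Judgement",
    "WEIGHT_SCALE",
    "RATING_SCALE",
]


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """Ordered triple (l, m, u) with l <= m <= u."""

    l: float
    m: float
    u: float

    def __post_init__(self) -> None:
        if not (self.l <= self.m <= self.u):
            raise ValueError(
                f"TFN components must satisfy l <= m <= u, got "
                f"({self.l}, {self.m}, {self.u})"
            )

    def __iter__(self) -> Iterator[float]:
        yield self.l
        yield self.m
        yield self.u

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.l, self.m, self.u)

    @property
    def is_crisp(self) -> bool:
        """True for a degenerate spike l == m == u (a crisp number)."""
        return self.l == self.m == self.u

    # -- operational laws ---------------------------------------------------

    def __add__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        return tfn_add(self, other)

    def __sub__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        return tfn_sub(self, other)

    def __mul__(
        self, other: Union["TriangularFuzzyNumber", float, int]
    ) -> "TriangularFuzzyNumber":
        if isinstance(other, TriangularFuzzyNumber):
            return tfn_mul(self, other)
        return tfn_scale(float(other), self)

    def __rmul__(self, other: Union[float, int]) -> "TriangularFuzzyNumber":
        return tfn_scale(float(other), self)

    def __repr__(self) -> str:
        return f"TFN({self.l:g}, {self.m:g}, {self.u:g})"


TFN = TriangularFuzzyNumber


def tfn_add(a: TFN, b: TFN) -> TFN:
    """Fuzzy sum: componentwise addition."""
    return TFN(a.l + b.l, a.m + b.m, a.u + b.u)


def tfn_sub(a: TFN, b: TFN) -> TFN:
    """Fuzzy difference (l1 - u2, m1 - m2, u1 - l2); always a valid triangle."""
    return TFN(a.l - b.u, a.m - b.m, a.u - b.l)


def tfn_mul(a: TFN, b: TFN) -> TFN:
    """Approximate fuzzy product (l1*l2, m1*m2, u1*u2).

    Valid (ordering-preserving) only for operands with nonnegative support;
    raises if the componentwise result is not a triangle.
    """
    try:
        return TFN(a.l * b.l, a.m * b.m, a.u * b.u)
    except ValueError:
        raise ValueError(
            "componentwise TFN product requires operands with nonnegative "
            f"support; got {a} * {b}"
        ) from None


def tfn_div(a: TFN, b: TFN) -> TFN:
    """Approximate fuzzy quotient (l1/u2, m1/m2, u1/l2); divisor support > 0."""
    if b.l <= 0:
        raise ValueError(f"TFN division requires divisor support l > 0, got {b}")
    try:
        return TFN(a.l / b.u, a.m / b.m, a.u / b.l)
    except ValueError:
        raise ValueError(
            "componentwise TFN quotient requires a dividend with nonnegative "
            f"support; got {a} / {b}"
        ) from None


def tfn_inv(a: TFN) -> TFN:
    """Approximate fuzzy reciprocal (1/u, 1/m, 1/l) for l > 0."""
    if a.l <= 0:
        raise ValueError(f"TFN inverse requires support l > 0, got {a}")
    return TFN(1.0 / a.u, 1.0 / a.m, 1.0 / a.l)


def tfn_scale(k: float, a: TFN) -> TFN:
    """Scale by a positive crisp factor k."""
    if k <= 0:
        raise ValueError(f"TFN scaling requires k > 0, got {k}")
    return TFN(k * a.l, k * a.m, k * a.u)


def membership(x: float, a: TFN) -> float:
    """Piecewise-linear membership degree of x in the TFN a, in [0, 1].

    Degenerate sides (l == m or m == u) return the limiting value 1 at the
    shared point, so a crisp spike acts as an indicator of equality.
    """
    if x < a.l or x > a.u:
        return 0.0
    if x == a.m:
        return 1.0
    if x < a.m:  # left slope; a.l < a.m here since x in [l, m)
        return (x - a.l) / (a.m - a.l)
    return (x - a.u) / (a.m - a.u)


def vertex_distance(a: TFN, b: TFN) -> float:
    """Vertex distance sqrt((1/3)[(la-lb)^2 + (ma-mb)^2 + (ua-ub)^2]).

    A metric on the triple space: the Euclidean distance between the vertex
    vectors, scaled so that d((0,0,0),(1,1,1)) = 1.
    """
    return math.sqrt(
        ((a.l - b.l) ** 2 + (a.m - b.m) ** 2 + (a.u - b.u) ** 2) / 3.0
    )


# -- linguistic scales ------------------------------------------------------


class CombineRule(Enum):
    """How a two-label judgement interval is collapsed into one TFN.

    The support always spans from the lower label's l to the upper label's u;
    the rule fixes the modal value.
    """

    MEAN_OF_MODALS = "mean"        # modal = (lo.m + hi.m) / 2
    MIDPOINT_OF_SUPPORT = "midpoint"  # modal = (lo.l + hi.u) / 2
    AS_GIVEN = "as_given"          # modal supplied explicitly with the judgement


@dataclass(frozen=True)
class LinguisticScale:
    """An ordered mapping from linguistic labels to TFNs.

    ``entries`` preserves insertion order, which defines the scale order used
    to validate judgement intervals (lo must precede hi).
    """

    name: str
    entries: Mapping[str, TFN]

    def __getitem__(self, label: str) -> TFN:
        try:
            return self.entries[label]
        except KeyError:
            raise KeyError(
                f"unknown label {label!r} on scale {self.name!r}; "
                f"known labels: {list(self.entries)}"
            ) from None

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def index(self, label: str) -> int:
        self[label]  # raise on unknown label
        return self.labels.index(label)

    @property
    def max_u(self) -> float:
        """Upper bound of the scale's support (top label's u)."""
        return max(t.u for t in self.entries.values())

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "labels": {lab: list(t.as_tuple()) for lab, t in self.entries.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinguisticScale":
        entries = {lab: TFN(*map(float, triple)) for lab, triple in d["labels"].items()}
        return cls(name=d["name"], entries=entries)


#: Seven-level scale for criterion weights, on [0, 1].
WEIGHT_SCALE = LinguisticScale(
    name="weights",
    entries={
        "VL": TFN(0.0, 0.0, 0.1),
        "L": TFN(0.0, 0.1, 0.3),
        "ML": TFN(0.1, 0.3, 0.5),
        "M": TFN(0.3, 0.5, 0.7),
        "MH": TFN(0.5, 0.7, 0.9),
        "H": TFN(0.7, 0.9, 1.0),
        "VH": TFN(0.9, 1.0, 1.0),
    },
)

#: Seven-level scale for alternative ratings, on [0, 10].
RATING_SCALE = LinguisticScale(
    name="ratings",
    entries={
        "VP": TFN(0.0, 0.0, 1.0),
        "P": TFN(0.0, 1.0, 3.0),
        "MP": TFN(1.0, 3.0, 5.0),
        "F": TFN(3.0, 5.0, 7.0),
        "MG": TFN(5.0, 7.0, 9.0),
        "G": TFN(7.0, 9.0, 10.0),
        "VG": TFN(9.0, 10.0, 10.0),
    },
)


@dataclass(frozen=True)
class Judgement:
    """A single expert judgement: a label, a label interval, or an explicit TFN.

    Exactly one of ``label``, ``interval`` or ``tfn`` is set.  ``modal`` is
    only meaningful for intervals resolved with :attr:`CombineRule.AS_GIVEN`.
    """

    label: str | None = None
    interval: tuple[str, str] | None = None
    tfn: TFN | None = None
    modal: float | None = None

    def __post_init__(self) -> None:
        n_set = sum(x is not None for x in (self.label, self.interval, self.tfn))
        if n_set != 1:
            raise ValueError(
                "exactly one of label, interval, tfn must be given "
                f"(got label={self.label!r}, interval={self.interval!r}, "
                f"tfn={self.tfn!r})"
            )
        if self.modal is not None and self.interval is None:
            raise ValueError("an explicit modal value only applies to intervals")

    @classmethod
    def from_label(cls, label: str) -> "Judgement":
        return cls(label=label)

    @classmethod
    def from_interval(
        cls, lo: str, hi: str, modal: float | None = None
    ) -> "Judgement":
        return cls(interval=(lo, hi), modal=modal)

    @classmethod
    def from_tfn(cls, tfn: TFN) -> "Judgement":
        return cls(tfn=tfn)

    def resolve(
        self,
        scale: LinguisticScale,
        combine_rule: CombineRule = CombineRule.MEAN_OF_MODALS,
    ) -> TFN:
        return resolve_judgement(self, scale, combine_rule)


def resolve_judgement(
    j: Judgement,
    scale: LinguisticScale,
    combine_rule: CombineRule = CombineRule.MEAN_OF_MODALS,
) -> TFN:
    """Turn a judgement into a TFN on the given scale.

    A single label maps to its scale TFN and an explicit TFN passes through.
    An interval (lo, hi) spans (lo.l, modal, hi.u), the modal value fixed by
    ``combine_rule``; a degenerate interval (lo == hi) collapses to the
    single-label result under every rule.  An interval judgement that carries
    its own explicit modal is resolved as given, whatever the rule — the
    recorded group consensus takes precedence over any recombination rule.
    """
    if j.tfn is not None:
        return j.tfn
    if j.label is not None:
        return scale[j.label]

    lo_lab, hi_lab = j.interval  # type: ignore[misc]
    lo, hi = scale[lo_lab], scale[hi_lab]
    if lo_lab == hi_lab:
        return lo
    if scale.index(lo_lab) > scale.index(hi_lab):
        raise ValueError(
            f"interval ({lo_lab}, {hi_lab}) must be ordered low-to-high on "
            f"scale {scale.name!r}"
        )
    if j.modal is not None:
        modal = j.modal
    elif combine_rule is CombineRule.MEAN_OF_MODALS:
        modal = (lo.m + hi.m) / 2.0
    elif combine_rule is CombineRule.MIDPOINT_OF_SUPPORT:
        modal = (lo.l + hi.u) / 2.0
    elif combine_rule is CombineRule.AS_GIVEN:
        raise ValueError(
            f"AS_GIVEN interval ({lo_lab}, {hi_lab}) requires an explicit "
            "modal value"
        )
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown combine rule {combine_rule!r}")
    if not (lo.l <= modal <= hi.u):
        raise ValueError(
            f"modal {modal} lies outside the interval support "
            f"[{lo.l}, {hi.u}] for ({lo_lab}, {hi_lab})"
        )
    return TFN(lo.l, modal, hi.u)
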