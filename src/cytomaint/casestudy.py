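"""The packaged hospital case study: one preparation hood and four policies.

The reference system is a laminar-flow hood with three sections in series
(filter, gas extraction, control with operating alarms); the failure and
repair rates were extracted from a hospital maintenance-management record.
The four maintenance alternatives map onto availability models as follows:

========  =======  ======================================================
Policy    n hoods  Failure pool
========  =======  ======================================================
CPM       1        all three sections (corrective + preventive)
CPM+C     2        all three sections, load shared over two hoods
CPM+2C    3        all three sections, load shared over three hoods
CPPM      1        filter section removed (outsourced thermographic
                   predictive maintenance prevents filter failures)
========  =======  ======================================================

The decision problem carries the hospital decision group's consensus
judgements over six criteria (two cost, four benefit) for those four
alternatives.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .io import problem_from_dict, system_from_dict
from .markov import RepairableSystem
from .topsis import DecisionProblem

__all__ = [
    "reference_system",
    "reference_problem",
    "alternative_systems",
    "ALTERNATIVES",
]

#: The four maintenance-policy alternatives, in presentation order.
ALTERNATIVES = ("CPM", "CPM+C", "CPM+2C", "CPPM")

_NON_FILTER = frozenset({"gas_extraction", "control_alarms"})


def _load_yaml(name: str) -> dict:
    with resources.files("cytomaint.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def reference_system(n_units: int = 1) -> RepairableSystem:
    """The three-section hood system with the recorded per-hour rates."""
    system = system_from_dict(_load_yaml("hospital_system.yaml"), "hospital_system")
    return system.with_units(n_units)


def reference_problem() -> DecisionProblem:
    """The consensus group-decision problem over the four alternatives."""
    return problem_from_dict(_load_yaml("hospital_problem.yaml"), "hospital_problem")


def alternative_systems() -> dict[str, RepairableSystem]:
    """Availability model per maintenance alternative."""
    base = reference_system()
    return {
        "CPM": base.with_units(1),
        "CPM+C": base.with_units(2),
        "CPM+2C": base.with_units(3),
        "CPPM": RepairableSystem(
            sections=base.sections,
            n_units=1,
            active_sections=_NON_FILTER,
            name=base.name,
        ),
    }
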