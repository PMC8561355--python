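"""YAML configuration I/O and CSV/markdown report writers.

Two document schemas are defined, both plain YAML with an explicit
``schema`` version field:

``cytomaint/system-v1``
    sections (name, failure_rate, repair_rate in per-hour units), n_units,
    optional active_sections.

``cytomaint/problem-v1``
    criteria (name, direction, optional descriptor), alternatives,
    decision_makers, and nested weight/rating judgements.  A judgement is a
    scale label (``"MG"``), a label interval (``"F-MG"``), an explicit
    triple (``[3, 6, 9]``), or a mapping ``{interval: [F, MG], modal: 6}``
    when the group recorded its own modal value for an interval.

Loaders validate eagerly and report the offending field; writers are the
exact inverse, so a dump/load round trip is the identity.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .fuzzy import TFN, Judgement
from .markov import AvailabilityResult, RepairableSystem, SectionRates
from .sensitivity import SensitivityReport
from .topsis import Criterion, DecisionProblem, Direction, PipelineOutput

__all__ = [
    "ConfigError",
    "SYSTEM_SCHEMA",
    "PROBLEM_SCHEMA",
    "load_system",
    "dump_system",
    "load_problem",
    "dump_problem",
    "parse_judgement",
    "judgement_to_config",
    "write_availability_report",
    "write_topsis_report",
    "write_sensitivity_report",
]

SYSTEM_SCHEMA = "cytomaint/system-v1"
PROBLEM_SCHEMA = "cytomaint/problem-v1"


class ConfigError(ValueError):
    """A configuration document failed validation."""


def _require(doc: Mapping, key: str, where: str) -> Any:
    if key not in doc:
        raise ConfigError(f"{where}: missing required field {key!r}")
    return doc[key]


def _check_schema(doc: Mapping, expected: str, where: str) -> None:
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{where}: expected a mapping at top level")
    schema = _require(doc, "schema", where)
    if schema != expected:
        raise ConfigError(
            f"{where}: schema {schema!r} does not match expected {expected!r}"
        )


# -- judgements -------------------------------------------------------------


def parse_judgement(value: Any, where: str) -> Judgement:
    """Parse one judgement config value (label, 'lo-hi', triple, or mapping)."""
    try:
        if isinstance(value, str):
            if "-" in value:
                lo, hi = value.split("-", 1)
                return Judgement.from_interval(lo.strip(), hi.strip())
            return Judgement.from_label(value.strip())
        if isinstance(value, (list, tuple)):
            if len(value) != 3:
                raise ValueError(f"a TFN triple needs 3 numbers, got {value!r}")
            return Judgement.from_tfn(TFN(*map(float, value)))
        if isinstance(value, Mapping):
            interval = _require(value, "interval", where)
            if len(interval) != 2:
                raise ValueError(f"interval needs two labels, got {interval!r}")
            modal = value.get("modal")
            return Judgement.from_interval(
                str(interval[0]), str(interval[1]),
                modal=None if modal is None else float(modal),
            )
    except ConfigError:
        raise
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{where}: invalid judgement {value!r}: {exc}") from exc
    raise ConfigError(f"{where}: cannot interpret judgement {value!r}")


def judgement_to_config(j: Judgement) -> Any:
    """Inverse of :func:`parse_judgement`."""
    if j.label is not None:
        return j.label
    if j.tfn is not None:
        return [j.tfn.l, j.tfn.m, j.tfn.u]
    lo, hi = j.interval  # type: ignore[misc]
    if j.modal is None:
        return f"{lo}-{hi}"
    return {"interval": [lo, hi], "modal": j.modal}


# -- repairable systems -----------------------------------------------------


def system_from_dict(doc: Mapping, where: str = "system config") -> RepairableSystem:
    _check_schema(doc, SYSTEM_SCHEMA, where)
    raw_sections = _require(doc, "sections", where)
    sections = []
    for i, sec in enumerate(raw_sections):
        sec_where = f"{where}: sections[{i}]"
        try:
            sections.append(
                SectionRates(
                    name=str(_require(sec, "name", sec_where)),
                    failure_rate=float(_require(sec, "failure_rate", sec_where)),
                    repair_rate=float(_require(sec, "repair_rate", sec_where)),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"{sec_where}: {exc}") from exc
    active = doc.get("active_sections")
    try:
        return RepairableSystem(
            sections=tuple(sections),
            n_units=int(doc.get("n_units", 1)),
            active_sections=None if active is None else frozenset(map(str, active)),
            name=str(doc.get("name", "")),
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def system_to_dict(system: RepairableSystem) -> dict:
    doc: dict = {
        "schema": SYSTEM_SCHEMA,
        "name": system.name,
        "n_units": system.n_units,
        "sections": [
            {
                "name": s.name,
                "failure_rate": s.failure_rate,
                "repair_rate": s.repair_rate,
            }
            for s in system.sections
        ],
    }
    if system.active_sections is not None:
        doc["active_sections"] = sorted(system.active_sections)
    return doc


def load_system(path: str | Path) -> RepairableSystem:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return system_from_dict(doc, where=str(path))


def dump_system(system: RepairableSystem, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(system_to_dict(system), fh, sort_keys=False)


# -- decision problems ------------------------------------------------------

_DIRECTIONS = {d.value: d for d in Direction}


def problem_from_dict(doc: Mapping, where: str = "problem config") -> DecisionProblem:
    _check_schema(doc, PROBLEM_SCHEMA, where)
    criteria = []
    for i, c in enumerate(_require(doc, "criteria", where)):
        c_where = f"{where}: criteria[{i}]"
        direction = str(_require(c, "direction", c_where))
        if direction not in _DIRECTIONS:
            raise ConfigError(
                f"{c_where}: direction must be one of {sorted(_DIRECTIONS)}, "
                f"got {direction!r}"
            )
        criteria.append(
            Criterion(
                name=str(_require(c, "name", c_where)),
                direction=_DIRECTIONS[direction],
                descriptor=str(c.get("descriptor", "")),
            )
        )
    alternatives = tuple(str(a) for a in _require(doc, "alternatives", where))
    makers = tuple(str(m) for m in _require(doc, "decision_makers", where))

    weights_doc = _require(doc, "weights", where)
    ratings_doc = _require(doc, "ratings", where)
    weight_judgements = {}
    rating_judgements = {}
    for dm in makers:
        dm_weights = _require(weights_doc, dm, f"{where}: weights")
        dm_ratings = _require(ratings_doc, dm, f"{where}: ratings")
        for c in criteria:
            weight_judgements[(dm, c.name)] = parse_judgement(
                _require(dm_weights, c.name, f"{where}: weights[{dm}]"),
                f"{where}: weights[{dm}][{c.name}]",
            )
        for alt in alternatives:
            alt_ratings = _require(dm_ratings, alt, f"{where}: ratings[{dm}]")
            for c in criteria:
                rating_judgements[(dm, alt, c.name)] = parse_judgement(
                    _require(alt_ratings, c.name, f"{where}: ratings[{dm}][{alt}]"),
                    f"{where}: ratings[{dm}][{alt}][{c.name}]",
                )
    try:
        return DecisionProblem(
            criteria=tuple(criteria),
            alternatives=alternatives,
            decision_makers=makers,
            weight_judgements=weight_judgements,
            rating_judgements=rating_judgements,
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def problem_to_dict(problem: DecisionProblem) -> dict:
    return {
        "schema": PROBLEM_SCHEMA,
        "criteria": [
            {"name": c.name, "direction": c.direction.value, "descriptor": c.descriptor}
            for c in problem.criteria
        ],
        "alternatives": list(problem.alternatives),
        "decision_makers": list(problem.decision_makers),
        "weights": {
            dm: {
                c.name: judgement_to_config(problem.weight_judgements[(dm, c.name)])
                for c in problem.criteria
            }
            for dm in problem.decision_makers
        },
        "ratings": {
            dm: {
                alt: {
                    c.name: judgement_to_config(
                        problem.rating_judgements[(dm, alt, c.name)]
                    )
                    for c in problem.criteria
                }
                for alt in problem.alternatives
            }
            for dm in problem.decision_makers
        },
    }


def load_problem(path: str | Path) -> DecisionProblem:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return problem_from_dict(doc, where=str(path))


def dump_problem(problem: DecisionProblem, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(problem_to_dict(problem), fh, sort_keys=False)


# -- reports ----------------------------------------------------------------


def write_availability_report(
    system: RepairableSystem,
    result: AvailabilityResult,
    out_dir: str | Path,
    ndigits: int = 4,
) -> Path:
    """CSV of (state, probability) plus a one-line availability summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    states_path = out_dir / "state_probabilities.csv"
    with open(states_path, "w") as fh:
        fh.write("state,probability\n")
        for i, p in enumerate(result.steady_state):
            fh.write(f"{i},{p!r}\n")
    summary = out_dir / "availability.txt"
    label = system.name or "system"
    summary.write_text(
        f"{label}: n_units={system.n_units} "
        f"mean_availability={result.rounded(ndigits):.{ndigits}f}\n"
    )
    return summary


def _markdown_table(frame) -> str:
    header = "| " + " | ".join(["alternative", *map(str, frame.columns)]) + " |"
    sep = "|" + "---|" * (len(frame.columns) + 1)
    rows = [
        "| " + " | ".join([str(idx), *map(str, row)]) + " |"
        for idx, row in zip(frame.index, frame.itertuples(index=False))
    ]
    return "\n".join([header, sep, *rows])


def write_topsis_report(
    output: PipelineOutput,
    out_dir: str | Path,
    ndigits_matrix: int = 3,
    ndigits_cc: int = 3,
) -> Path:
    """CSV files for every pipeline stage plus a markdown summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with open(out_dir / "weights.csv", "w") as fh:
        fh.write("criterion,l,m,u\n")
        for crit, w in output.weights.items():
            fh.write(f"{crit},{w.l:.{ndigits_matrix}f},{w.m:.{ndigits_matrix}f},{w.u:.{ndigits_matrix}f}\n")
    for stage in ("aggregated", "normalised", "weighted"):
        getattr(output, stage).to_frame(ndigits_matrix).to_csv(
            out_dir / f"{stage}.csv", index_label="alternative"
        )
    result_frame = output.result.to_frame(ndigits_cc)
    result_frame.to_csv(out_dir / "result.csv", index_label="alternative")

    md = [
        "# Fuzzy TOPSIS report",
        "",
        "## Weighted normalised matrix",
        "",
        _markdown_table(output.weighted.to_frame(ndigits_matrix)),
        "",
        "## Separations and closeness",
        "",
        _markdown_table(result_frame),
        "",
        "Ranking: " + " > ".join(output.result.ranking),
        "",
    ]
    path = out_dir / "report.md"
    path.write_text("\n".join(md))
    return path


def write_sensitivity_report(
    report: SensitivityReport,
    out_dir: str | Path,
    ndigits: int = 3,
    plot: bool = False,
) -> Path:
    """CSV of all perturbation scenarios; optional per-criterion bar charts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame(ndigits)
    path = out_dir / "sensitivity.csv"
    frame.to_csv(path, index=False)
    (out_dir / "stable.txt").write_text(f"stable: {report.stable}\n")
    if plot:
        _plot_sensitivity(report, out_dir)
    return path


def _plot_sensitivity(report: SensitivityReport, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    criteria = sorted({s.criterion for s in report.scenarios})
    alts = list(report.baseline.cc)
    for crit in criteria:
        scen = [s for s in report.scenarios if s.criterion == crit]
        fig, ax = plt.subplots(figsize=(6, 3.5))
        width = 0.8 / len(alts)
        for k, alt in enumerate(alts):
            xs = [i + k * width for i in range(len(scen))]
            ax.bar(xs, [s.cc[alt] for s in scen], width=width, label=alt)
        ax.set_xticks([i + 0.4 for i in range(len(scen))])
        ax.set_xticklabels([f"{s.delta:+.0%}" for s in scen])
        ax.set_ylabel("closeness coefficient")
        ax.set_title(f"Weight perturbation: {crit}")
        ax.legend(fontsize="small")
        fig.tight_layout()
        fig.savefig(out_dir / f"sensitivity_{crit}.png", dpi=100)
        plt.close(fig)
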