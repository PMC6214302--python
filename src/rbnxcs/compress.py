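"""Numerosity-ordered compact-ruleset post-processing.

After training, the population is sorted by numerosity (classifiers the GA
has reproduced and merged most often come first) and evaluated as a
standalone greedy controller at every prefix length.  For completeness all
prefixes are examined; among the fully state-space-covering prefixes the one
with the minimum average number of interventions is the compact rule set.
Rules are returned verbatim — compaction never edits a classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .environment import ControlTask, EvaluationReport, evaluate_all_states
from .xcs import Classifier, Population

__all__ = ["CompactionResult", "compact_ruleset", "numerosity_order"]


def numerosity_order(rules: Sequence[Classifier]) -> list[Classifier]:
    """Sort by numerosity desc, then fitness, prediction, condition, action."""
    return sorted(
        rules,
        key=lambda c: (
            -c.numerosity,
            -c.fitness,
            -c.prediction,
            c.condition,
            c.action,
        ),
    )


@dataclass(frozen=True)
class CompactionResult:
    """The chosen compact rule set and the per-prefix evaluation trail."""

    ruleset: tuple[Classifier, ...]
    covered: bool
    avg_steps: float
    avg_interventions: float
    prefix_reports: tuple[EvaluationReport, ...]

    @property
    def size(self) -> int:
        return len(self.ruleset)


def compact_ruleset(
    pop: Population | Sequence[Classifier],
    task: ControlTask,
    max_steps: int | None = None,
) -> CompactionResult:
    """Minimum-average-intervention fully covering prefix of the population.

    Macroclassifiers are ordered by numerosity (ties: fitness, prediction,
    condition, action) and every prefix 1..M is evaluated from all start
    states.  Among covering prefixes the one minimising the average number
    of interventions wins, ties going to the smaller prefix.  If no prefix
    covers the state space, the result is flagged ``covered=False`` and
    carries the full ordered rule list with its evaluation.
    """
    rules = pop.classifiers() if isinstance(pop, Population) else list(pop)
    if not rules:
        raise ValueError("cannot compact an empty population")
    ordered = numerosity_order(rules)
    reports: list[EvaluationReport] = []
    best_k = -1
    best_report: EvaluationReport | None = None
    for k in range(1, len(ordered) + 1):
        report = evaluate_all_states(task, ordered[:k], max_steps)
        reports.append(report)
        if report.covered and (
            best_report is None
            or report.avg_interventions < best_report.avg_interventions
        ):
            best_k = k
            best_report = report
    if best_report is None:
        full = reports[-1]
        return CompactionResult(
            ruleset=tuple(ordered),
            covered=False,
            avg_steps=full.avg_steps,
            avg_interventions=full.avg_interventions,
            prefix_reports=tuple(reports),
        )
    return CompactionResult(
        ruleset=tuple(ordered[:best_k]),
        covered=True,
        avg_steps=best_report.avg_steps,
        avg_interventions=best_report.avg_interventions,
        prefix_reports=tuple(reports),
    )
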