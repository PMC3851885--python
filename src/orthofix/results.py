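"""Shared result container for the two correction algorithms."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .reconcile import DUPLICATION, ReconciledGeneTree


@dataclass
class CorrectionResult:
    """A corrected gene tree plus diagnostics.

    ``rf_to_input`` is the Robinson-Foulds distance counted in both
    directions, i.e. twice the number of input clades lost.
    ``forbidden_count`` is |H| for pair-constraint corrections and None for
    clade-constraint corrections, which set ``pushed_clades`` instead.
    """

    corrected: ReconciledGeneTree
    rf_to_input: int
    forbidden_count: int | None = None
    pushed_clades: list[frozenset[str]] | None = None
    constraint_report: list[dict[str, Any]] = field(default_factory=list)
    lost_clades: list[frozenset[str]] = field(default_factory=list)
    input_duplications: int = 0
    output_duplications: int = 0

    @property
    def all_satisfied(self) -> bool:
        return all(entry["satisfied"] for entry in self.constraint_report)

    def newick(self) -> str:
        return self.corrected.tree.newick()

    def to_report(self, problem: str) -> dict[str, Any]:
        """JSON-serializable report (schema orthofix-report/1)."""
        rep: dict[str, Any] = {
            "schema": "orthofix-report/1",
            "problem": problem,
            "rf": self.rf_to_input,
            "corrected_newick": self.newick(),
            "lost_clades": [sorted(c) for c in sorted(self.lost_clades, key=sorted)],
            "constraints": self.constraint_report,
            "all_satisfied": self.all_satisfied,
            "input_duplications": self.input_duplications,
            "output_duplications": self.output_duplications,
        }
        if self.forbidden_count is not None:
            rep["forbidden_count"] = self.forbidden_count
        if self.pushed_clades is not None:
            rep["pushed_clades"] = [sorted(c) for c in self.pushed_clades]
        return rep


def count_duplications(R: ReconciledGeneTree) -> int:
    return sum(1 for n in R.tree.nodes() if R.event[n] == DUPLICATION)
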