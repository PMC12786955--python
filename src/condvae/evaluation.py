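"""Precision-at-k evaluation over full and per-component condition matches.

p@k is the percentage of test reactions for which at least one recorded
condition combination appears, as an exact bitstring match, within the top-k
predictions: p@k = 100·n@k/N. Component precisions (catalyst c@k, additives
ad@k, temperature t@k, pressure) compare only the corresponding block of the
bitstring; the additive block must match as a complete multi-hot subset.
Since a full-vector match implies a match of every block, the overall p@k
never exceeds any component precision at the same k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import RankedConditionList

__all__ = ["EvaluationReport", "precision_at_k", "component_precision",
           "evaluate_models", "DEFAULT_K_GRID"]

DEFAULT_K_GRID = (1, 2, 3, 5, 10, 25, 50, 100)

COMPONENTS = ("catalyst", "additives", "temp", "pressure")


@dataclass
class EvaluationReport:
    """Per-k table of overall and per-component precisions (percent)."""

    n_reactions: int
    k_grid: tuple[int, ...]
    overall: dict[int, float]
    components: dict[str, dict[int, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_reactions": self.n_reactions,
            "k_grid": list(self.k_grid),
            "p_at_k": {str(k): v for k, v in self.overall.items()},
            "components": {c: {str(k): v for k, v in table.items()}
                           for c, table in self.components.items()},
        }


def _check_coverage(predictions: dict, truths: dict) -> None:
    missing = set(truths) - set(predictions)
    if missing:
        raise ValueError(f"missing prediction lists for reactions: {sorted(missing)[:5]}")
    for rid, tset in truths.items():
        if not tset:
            raise ValueError(f"reaction {rid!r} has no recorded truth condition")


def precision_at_k(predictions: dict[str, RankedConditionList],
                   truths: dict[str, set], k: int) -> float:
    """Percentage of reactions with ≥1 exact full-vector truth in the top-k."""
    _check_coverage(predictions, truths)
    n_hit = 0
    for rid, tset in truths.items():
        top = predictions[rid].top(k)
        if any(v in tset for v in top):
            n_hit += 1
    return 100.0 * n_hit / len(truths)


def component_precision(predictions: dict[str, RankedConditionList],
                        truths: dict[str, set], component: str, k: int) -> float:
    """p@k restricted to one block of the bitstring.

    `component` is one of catalyst|additives|temp|pressure. The additive
    block counts as correct only when the full multi-hot set matches.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}; expected one of {COMPONENTS}")
    _check_coverage(predictions, truths)
    n_hit = 0
    for rid, tset in truths.items():
        truth_blocks = {t.block(component) for t in tset}
        top_blocks = [v.block(component) for v in predictions[rid].top(k)]
        if any(b in truth_blocks for b in top_blocks):
            n_hit += 1
    return 100.0 * n_hit / len(truths)


def evaluate_models(predictions: dict[str, RankedConditionList],
                    truths: dict[str, set],
                    k_grid=DEFAULT_K_GRID) -> EvaluationReport:
    """Full report: overall p@k plus all four component precisions."""
    k_grid = tuple(k_grid)
    overall = {k: precision_at_k(predictions, truths, k) for k in k_grid}
    components = {c: {k: component_precision(predictions, truths, c, k)
                      for k in k_grid} for c in COMPONENTS}
    return EvaluationReport(n_reactions=len(truths), k_grid=k_grid,
                            overall=overall, components=components)
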