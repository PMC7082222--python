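"""Condensation of individual test metrics into section and overall scores.

Within a section the score is a weighted mean of the scored test metrics,
scaled to [0, 100]; the overall score is the weighted mean of the section
scores.  Consistency carries triple section weight, the stoichiometric-
consistency test triple test weight and SBO-coverage tests double test
weight — the package's concretization of the qualitative weighting rule
that consistency and SBO coverage matter more than cross-reference
completeness.  All weights are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .config import Config
from .results import ResultSet

__all__ = ["ScoreBreakdown", "compute_score"]


@dataclass
class ScoreBreakdown:
    sections: Dict[str, Optional[float]]           # section -> score in [0, 100]
    section_weights: Dict[str, float]
    contributions: Dict[str, Dict[str, float]]     # section -> test_id -> weighted share
    overall: Optional[float]
    unscored_tests: List[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.overall is not None


def compute_score(result_set: ResultSet, config: Optional[Config] = None) -> ScoreBreakdown:
    """Weighted two-level condensation of a result set.

    section = Σ_t w_t·metric_t / Σ_t w_t × 100 over the section's scored
    tests; overall = Σ_s w_s·section_s / Σ_s w_s over sections that have
    at least one scored test.  Unscored tests are excluded and listed.
    """
    config = config or Config()
    if not result_set.results:
        raise ValueError("cannot score an empty result set")
    by_section: Dict[str, list] = {}
    unscored = []
    for result in result_set.results:
        if result.scored and result.metric is not None:
            by_section.setdefault(result.section, []).append(result)
        else:
            unscored.append(result.test_id)
    sections: Dict[str, Optional[float]] = {}
    contributions: Dict[str, Dict[str, float]] = {}
    for section, tests in by_section.items():
        weights = {
            t.test_id: config.test_weights.get(t.test_id, t.weight) for t in tests
        }
        total_weight = sum(weights.values())
        score = 100.0 * sum(weights[t.test_id] * t.metric for t in tests) / total_weight
        sections[section] = score
        contributions[section] = {
            t.test_id: 100.0 * weights[t.test_id] * t.metric / total_weight for t in tests
        }
    if not sections:
        return ScoreBreakdown(sections={}, section_weights={}, contributions={},
                              overall=None, unscored_tests=sorted(unscored))
    section_weights = {
        s: config.section_weights.get(s, 1.0) for s in sections
    }
    total = sum(section_weights.values())
    overall = sum(section_weights[s] * sections[s] for s in sections) / total
    return ScoreBreakdown(
        sections=sections,
        section_weights=section_weights,
        contributions=contributions,
        overall=overall,
        unscored_tests=sorted(unscored),
    )
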