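"""Result containers: one test outcome and the collection for a model run."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any, Dict, List, Optional

__all__ = ["TestResult", "ResultSet", "SECTIONS"]

SECTIONS = ("annotation", "basic", "biomass", "consistency", "experimental")


@dataclass
class TestResult:
    __test__ = False  # not a pytest class, despite the domain name

    test_id: str
    section: str
    metric: Optional[float] = None  # fraction in [0, 1]; 1 = perfect; None = unscored
    data: List[Any] = field(default_factory=list)
    message: str = ""
    scored: bool = True
    weight: float = 1.0

    def __post_init__(self):
        if self.section not in SECTIONS:
            raise ValueError(f"unknown section {self.section!r}")
        if self.metric is not None and not (0.0 <= self.metric <= 1.0 + 1e-12):
            raise ValueError(f"metric out of [0, 1]: {self.metric}")
        if self.metric is None:
            self.scored = False

    def to_dict(self) -> Dict[str, Any]:
        return {
            "test_id": self.test_id,
            "section": self.section,
            "metric": self.metric,
            "data": self.data,
            "message": self.message,
            "scored": self.scored,
            "weight": self.weight,
        }

    @classmethod
    def from_dict(cls, raw: Dict[str, Any]) -> "TestResult":
        return cls(**raw)


@dataclass
class ResultSet:
    model_id: str
    digest: str
    results: List[TestResult] = field(default_factory=list)
    timestamp: str = ""
    tool_version: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        ids = [r.test_id for r in self.results]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate test_ids in result set")

    def get(self, test_id: str) -> TestResult:
        for result in self.results:
            if result.test_id == test_id:
                return result
        raise KeyError(test_id)

    def scored_results(self) -> List[TestResult]:
        return [r for r in self.results if r.scored and r.metric is not None]

    def to_dict(self) -> Dict[str, Any]:
        return {
            "model_id": self.model_id,
            "digest": self.digest,
            "timestamp": self.timestamp,
            "tool_version": self.tool_version,
            "results": [r.to_dict() for r in self.results],
        }

    @classmethod
    def from_dict(cls, raw: Dict[str, Any]) -> "ResultSet":
        return cls(
            model_id=raw["model_id"],
            digest=raw["digest"],
            timestamp=raw.get("timestamp", ""),
            tool_version=raw.get("tool_version", ""),
            results=[TestResult.from_dict(r) for r in raw["results"]],
        )

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ResultSet":
        return cls.from_dict(json.loads(text))
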