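"""Diagnosis reports and their JSON serialisation."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

__all__ = ["RatingHistogram", "DiagnosisReport"]

#: status values a report can carry
STATUS_OK = "ok"
STATUS_REFUSED = "refused"


@dataclass
class RatingHistogram:
    """Percentage of assigned voxels per condition.

    ``percentages`` sums to 100 over conditions whenever at least one voxel
    is assigned; unassigned voxels are counted separately and never enter
    the histogram.  ``separation`` (top bin minus runner-up bin, in
    percentage points) is a confidence proxy.
    """

    percentages: dict[str, float]
    n_assigned: int
    n_unassigned: int
    separation: Optional[float]

    @classmethod
    def from_counts(cls, counts: dict[str, int], n_unassigned: int) -> "RatingHistogram":
        total = sum(counts.values())
        if total == 0:
            return cls({}, 0, int(n_unassigned), None)
        pct = {c: 100.0 * n / total for c, n in counts.items()}
        ordered = sorted(pct.values(), reverse=True)
        runner_up = ordered[1] if len(ordered) > 1 else 0.0
        return cls(pct, int(total), int(n_unassigned), ordered[0] - runner_up)

    @property
    def empty(self) -> bool:
        return self.n_assigned == 0

    def argmax(self) -> Optional[str]:
        if self.empty:
            return None
        # deterministic tie-break by condition name
        return min(self.percentages, key=lambda c: (-self.percentages[c], c))


@dataclass
class DiagnosisReport:
    """Outcome of a single diagnosis: chosen condition plus evidence.

    ``histogram`` is populated for the rating-map method, ``ncc_scores`` for
    the image-synthesis method.
    """

    method: str
    predicted: Optional[str]
    status: str = STATUS_OK
    histogram: Optional[RatingHistogram] = None
    ncc_scores: Optional[dict[str, float]] = None
    parameters: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "DiagnosisReport":
        hist = d.get("histogram")
        return cls(
            method=d["method"],
            predicted=d.get("predicted"),
            status=d.get("status", STATUS_OK),
            histogram=RatingHistogram(**hist) if hist else None,
            ncc_scores=d.get("ncc_scores"),
            parameters=d.get("parameters", {}),
            warnings=list(d.get("warnings", [])),
        )

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "DiagnosisReport":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls.from_dict(json.loads(text))
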