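"""ACT-score risk labels and window alignment.

The Asthma Control Test (ACT) yields an integer total score from 5 (worst)
to 25 (fully controlled).  Scores bin into three risk levels:

    low    20-25   (well controlled)
    medium 15-19   (not as well controlled as it could be)
    high    5-14   (poorly controlled)

The published ranges list 19 under both low and medium; it is resolved to
medium, consistent with "19 or less" marking imperfect control.  Hourly ACT
observations are aligned to classification windows by the nearest
observation within +/-30 min of the window end (half the hourly cadence);
windows without one are left unlabeled and excluded from training.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "ACT_MIN",
    "ACT_MAX",
    "RiskLevel",
    "ACTObservation",
    "act_to_risk",
    "align_labels",
    "read_act_table",
    "write_act_table",
]

ACT_MIN = 5
ACT_MAX = 25

#: Default alignment horizon: half the hourly ACT cadence, seconds.
DEFAULT_LABEL_HORIZON_S = 30 * 60.0


class RiskLevel(str, enum.Enum):
    """Three-level asthma-attack risk, totally ordered high > medium > low."""

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"

    @property
    def rank(self) -> int:
        return {"low": 0, "medium": 1, "high": 2}[self.value]

    def __lt__(self, other: "RiskLevel") -> bool:  # type: ignore[override]
        if not isinstance(other, RiskLevel):
            return NotImplemented
        return self.rank < other.rank


#: Class order used for model output columns and confusion matrices.
RISK_ORDER: tuple[RiskLevel, ...] = (RiskLevel.LOW, RiskLevel.MEDIUM, RiskLevel.HIGH)


@dataclass(frozen=True)
class ACTObservation:
    """One ACT administration: epoch-second timestamp and total score."""

    t: float
    score: int

    def __post_init__(self) -> None:
        if int(self.score) != self.score:
            raise ValueError(f"ACT score must be an integer, got {self.score!r}")
        object.__setattr__(self, "score", int(self.score))
        if not ACT_MIN <= self.score <= ACT_MAX:
            raise ValueError(
                f"ACT score must be in [{ACT_MIN}, {ACT_MAX}], got {self.score}"
            )


def act_to_risk(score: int) -> RiskLevel:
    """Map an ACT total score to its risk level (low 20-25, medium 15-19,
    high <= 14)."""
    if int(score) != score:
        raise ValueError(f"ACT score must be an integer, got {score!r}")
    score = int(score)
    if not ACT_MIN <= score <= ACT_MAX:
        raise ValueError(f"ACT score must be in [{ACT_MIN}, {ACT_MAX}], got {score}")
    if score >= 20:
        return RiskLevel.LOW
    if score >= 15:
        return RiskLevel.MEDIUM
    return RiskLevel.HIGH


def align_labels(
    windows: Sequence[tuple[float, float]],
    acts: Sequence[ACTObservation],
    horizon_s: float = DEFAULT_LABEL_HORIZON_S,
) -> list[Optional[RiskLevel]]:
    """Label each window by the nearest ACT observation to its end time.

    An observation qualifies when ``|t_act - window_end| <= horizon_s``;
    exact distance ties break toward the earlier observation.  Windows with
    no qualifying observation get ``None`` (reported, not fatal) and are
    excluded from training downstream.
    """
    acts = sorted(acts, key=lambda a: a.t)
    labels: list[Optional[RiskLevel]] = []
    import bisect

    ts = [a.t for a in acts]
    for _, end in windows:
        if not acts:
            labels.append(None)
            continue
        i = bisect.bisect_left(ts, end)
        candidates = []
        if i > 0:
            candidates.append(acts[i - 1])
        if i < len(acts):
            candidates.append(acts[i])
        # min() keeps the first (earlier) candidate on distance ties
        best = min(candidates, key=lambda a: abs(a.t - end))
        labels.append(act_to_risk(best.score) if abs(best.t - end) <= horizon_s else None)
    return labels


def read_act_table(path: str | Path) -> list[ACTObservation]:
    """Read ACT observations from a CSV with header ``t,score``."""
    out: list[ACTObservation] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(ACTObservation(t=float(row["t"]), score=int(row["score"])))
    return out


def write_act_table(acts: Sequence[ACTObservation], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "score"])
        for act in sorted(acts, key=lambda a: a.t):
            writer.writerow([repr(act.t), act.score])
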