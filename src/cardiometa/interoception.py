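"""Heartbeat-counting interoceptive accuracy (Schandry tracking index).

Subjects silently count their heartbeats over timed intervals while the true
beat count is recorded from a pulse transducer.  Accuracy per interval is
1 - |recorded - counted| / recorded, and the subject's score is the unweighted
mean across intervals: 1 for perfect counting, 0 for counting nothing, and
negative if a subject overcounts beyond twice the recorded beats (kept as
computed, with a logged warning, rather than silently clamped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .io_model import CountingRecord

logger = logging.getLogger("cardiometa")

__all__ = ["IAccScore", "schandry_index"]


@dataclass(frozen=True)
class IAccScore:
    subject_id: str
    score: float
    per_interval: tuple[float, ...]


def schandry_index(records: Sequence[CountingRecord]) -> IAccScore:
    """Mean heartbeat-tracking accuracy over the supplied intervals."""
    if not records:
        raise ValueError("need at least one counting record")
    subject_id = records[0].subject_id
    per_interval = []
    for r in records:
        if r.subject_id != subject_id:
            raise ValueError(
                f"records mix subjects {subject_id!r} and {r.subject_id!r}"
            )
        acc = 1.0 - abs(r.recorded - r.counted) / r.recorded
        if acc < 0:
            logger.warning(
                "subject %s overcounted interval %.0fs (%d counted vs %d recorded); "
                "negative interval accuracy %.3f retained",
                subject_id, r.interval_s, r.counted, r.recorded, acc,
            )
        per_interval.append(acc)
    score = sum(per_interval) / len(per_interval)
    return IAccScore(subject_id=subject_id, score=score,
                     per_interval=tuple(per_interval))
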