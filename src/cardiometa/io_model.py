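"""Data model, file I/O and validation for trial-level and counting-task records.

The interchange formats are delimited text (comma default, tab accepted):

* trials file:   ``subject_id,trial_index,stimulus,response,confidence``
* counting file: ``subject_id,interval_s,counted,recorded``

``stimulus`` is ``self``/``other`` (whose heart produced the sound),
``response`` is ``self``/``other`` (the forced-choice answer), and
``confidence`` is a visual-analogue rating in [0, 100].
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("cardiometa")

__all__ = [
    "Stimulus",
    "Response",
    "TaskTag",
    "RateCorrection",
    "TrialRecord",
    "CountingRecord",
    "SubjectDataset",
    "AnalysisConfig",
    "SchemaError",
    "ValidationError",
    "read_trials",
    "write_trials",
    "read_counting",
    "write_counting",
    "write_report",
    "read_report",
    "round_half_away",
]


class SchemaError(ValueError):
    """A file does not match the documented column schema."""


class ValidationError(ValueError):
    """A record violates a domain invariant; message cites the offending row."""


class Stimulus(enum.Enum):
    SELF_HEART = "self"
    OTHER_HEART = "other"


class Response(enum.Enum):
    SAYS_SELF = "self"
    SAYS_OTHER = "other"


class TaskTag(enum.Enum):
    HEART_SOUND = "heart"
    BEEP_CONTROL = "beep"


class RateCorrection(enum.Enum):
    """Correction applied to type-1 hit/false-alarm rates before the z-transform."""

    LOGLIN = "loglin"  # add 0.5 to all four type-1 cells
    HALF_COUNT = "half_count"  # replace 0 with 1/(2N), 1 with 1 - 1/(2N)
    NONE = "none"


@dataclass(frozen=True)
class TrialRecord:
    """One forced-choice trial: stimulus truth, response, confidence rating."""

    subject_id: str
    trial_index: int
    stimulus: Stimulus
    response: Response
    confidence: float

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValidationError(
                f"trial_index must be >= 1, got {self.trial_index} "
                f"(subject {self.subject_id})"
            )
        if not (0.0 <= self.confidence <= 100.0) or math.isnan(self.confidence):
            raise ValidationError(
                f"confidence must lie in [0, 100], got {self.confidence} "
                f"(subject {self.subject_id}, trial {self.trial_index})"
            )

    @property
    def correct(self) -> bool:
        return (self.stimulus is Stimulus.SELF_HEART) == (
            self.response is Response.SAYS_SELF
        )


@dataclass(frozen=True)
class CountingRecord:
    """One heartbeat-counting interval: reported vs. actually recorded beats."""

    subject_id: str
    interval_s: float
    counted: int
    recorded: int

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ValidationError(
                f"interval_s must be > 0, got {self.interval_s} "
                f"(subject {self.subject_id})"
            )
        if self.counted < 0:
            raise ValidationError(
                f"counted must be >= 0, got {self.counted} (subject {self.subject_id})"
            )
        if self.recorded < 1:
            raise ValidationError(
                f"recorded must be >= 1, got {self.recorded} "
                f"(subject {self.subject_id})"
            )


@dataclass
class SubjectDataset:
    """All trials (and optional counting records) for one subject."""

    subject_id: str
    trials: list[TrialRecord]
    counting: list[CountingRecord] = field(default_factory=list)
    task_tag: TaskTag = TaskTag.HEART_SOUND

    def __post_init__(self) -> None:
        for t in self.trials:
            if t.subject_id != self.subject_id:
                raise ValidationError(
                    f"trial subject_id {t.subject_id!r} does not match dataset "
                    f"subject {self.subject_id!r}"
                )
        for c in self.counting:
            if c.subject_id != self.subject_id:
                raise ValidationError(
                    f"counting subject_id {c.subject_id!r} does not match dataset "
                    f"subject {self.subject_id!r}"
                )
        idx = [t.trial_index for t in self.trials]
        if len(set(idx)) != len(idx):
            dupes = sorted({i for i in idx if idx.count(i) > 1})
            raise ValidationError(
                f"duplicate trial_index {dupes} for subject {self.subject_id}"
            )
        n_self = sum(t.stimulus is Stimulus.SELF_HEART for t in self.trials)
        n_other = len(self.trials) - n_self
        if self.trials and n_self != n_other:
            logger.warning(
                "subject %s has unbalanced stimuli (%d self / %d other); "
                "binomial model will use the actual trial count",
                self.subject_id,
                n_self,
                n_other,
            )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_correct(self) -> int:
        return sum(t.correct for t in self.trials)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_trials


@dataclass
class AnalysisConfig:
    """Pipeline configuration.

    Parameters
    ----------
    n_trials_expected : expected trials per subject (deviations are warned about).
    alpha_chance : significance level of the binomial chance criterion.
    n_confidence_bins : number of confidence levels K used for the type-2 model.
    rate_correction : type-1 rate correction scheme.
    seed : seed for the meta-d' fit restarts (and any other pipeline randomness).
    n_restarts : random restarts for the meta-d' optimizer.
    """

    n_trials_expected: int = 30
    alpha_chance: float = 0.05
    n_confidence_bins: int = 4
    rate_correction: RateCorrection = RateCorrection.LOGLIN
    seed: int = 0
    n_restarts: int = 8

    def __post_init__(self) -> None:
        if isinstance(self.rate_correction, str):
            self.rate_correction = RateCorrection(self.rate_correction.lower())
        if self.n_confidence_bins < 2:
            raise ValidationError(
                f"n_confidence_bins must be >= 2, got {self.n_confidence_bins}"
            )
        if not (0.0 < self.alpha_chance < 1.0):
            raise ValidationError(
                f"alpha_chance must lie in (0, 1), got {self.alpha_chance}"
            )
        if self.n_trials_expected < 1:
            raise ValidationError("n_trials_expected must be >= 1")
        if self.n_restarts < 1:
            raise ValidationError("n_restarts must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "n_trials_expected": self.n_trials_expected,
            "alpha_chance": self.alpha_chance,
            "n_confidence_bins": self.n_confidence_bins,
            "rate_correction": self.rate_correction.value,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
        }


# ---------------------------------------------------------------------------
# file I/O


_TRIAL_COLUMNS = ["subject_id", "trial_index", "stimulus", "response", "confidence"]
_COUNTING_COLUMNS = ["subject_id", "interval_s", "counted", "recorded"]

_STIM_TOKENS = {
    "self": Stimulus.SELF_HEART,
    "self_heart": Stimulus.SELF_HEART,
    "other": Stimulus.OTHER_HEART,
    "other_heart": Stimulus.OTHER_HEART,
}
_RESP_TOKENS = {
    "self": Response.SAYS_SELF,
    "says_self": Response.SAYS_SELF,
    "other": Response.SAYS_OTHER,
    "says_other": Response.SAYS_OTHER,
}


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # sep=None sniffs comma vs tab from the header line
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def read_trials(
    path: str | Path, task_tag: TaskTag = TaskTag.HEART_SOUND
) -> list[SubjectDataset]:
    """Read a trials file into one validated :class:`SubjectDataset` per subject.

    Subjects appear in first-occurrence order; trials keep file order.
    Raises :class:`SchemaError` for missing columns and :class:`ValidationError`
    (citing the 1-based data row) for malformed values. Validation is total:
    a bad row aborts the load, never yielding a partial cohort.
    """
    df = _read_table(path, _TRIAL_COLUMNS)
    by_subject: dict[str, list[TrialRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            stim = _STIM_TOKENS[str(row.stimulus).strip().lower()]
        except KeyError:
            raise ValidationError(
                f"{path}: row {i}: unknown stimulus {row.stimulus!r} "
                "(expected 'self' or 'other')"
            ) from None
        try:
            resp = _RESP_TOKENS[str(row.response).strip().lower()]
        except KeyError:
            raise ValidationError(
                f"{path}: row {i}: unknown response {row.response!r} "
                "(expected 'self' or 'other')"
            ) from None
        try:
            rec = TrialRecord(
                subject_id=str(row.subject_id),
                trial_index=int(row.trial_index),
                stimulus=stim,
                response=resp,
                confidence=float(row.confidence),
            )
        except ValidationError as e:
            raise ValidationError(f"{path}: row {i}: {e}") from None
        except (TypeError, ValueError) as e:
            raise ValidationError(f"{path}: row {i}: {e}") from None
        by_subject.setdefault(rec.subject_id, []).append(rec)
    datasets = []
    for sid, trials in by_subject.items():
        try:
            datasets.append(SubjectDataset(sid, trials, task_tag=task_tag))
        except ValidationError as e:
            raise ValidationError(f"{path}: {e}") from None
    return datasets


def write_trials(datasets: Iterable[SubjectDataset], path: str | Path) -> None:
    """Write datasets back to the delimited trials format (inverse of read_trials)."""
    rows = [
        {
            "subject_id": t.subject_id,
            "trial_index": t.trial_index,
            "stimulus": t.stimulus.value,
            "response": t.response.value,
            "confidence": t.confidence,
        }
        for ds in datasets
        for t in ds.trials
    ]
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(path, index=False)


def read_counting(path: str | Path) -> list[CountingRecord]:
    """Read a heartbeat-counting file; intervals need not be the canonical four."""
    df = _read_table(path, _COUNTING_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                CountingRecord(
                    subject_id=str(row.subject_id),
                    interval_s=float(row.interval_s),
                    counted=int(float(row.counted)),
                    recorded=int(float(row.recorded)),
                )
            )
        except ValidationError as e:
            raise ValidationError(f"{path}: row {i}: {e}") from None
        except (TypeError, ValueError) as e:
            raise ValidationError(f"{path}: row {i}: {e}") from None
    return records


def write_counting(records: Iterable[CountingRecord], path: str | Path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "interval_s": r.interval_s,
            "counted": r.counted,
            "recorded": r.recorded,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_COUNTING_COLUMNS).to_csv(path, index=False)


def write_report(results: dict, path: str | Path) -> None:
    """Write the pipeline result structure as a JSON report.

    Re-reading with :func:`read_report` yields an identical structure.
    """
    if not results.get("per_subject"):
        raise ValidationError("no subjects in results; refusing to write empty report")
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=False, allow_nan=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report display convention)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
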