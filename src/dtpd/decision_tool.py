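"""The DTPD scoring rule.

Seven yes/no criteria (the last two also allow "not applicable"), a sum
score, a cut-off (default 4), and a gate question: patients at or above the
cut-off are referred to highly specialized care if the gate question —
possibility and motivation to conform to minimal treatment conditions — is
answered yes or is not applicable, and not referred if it is answered no.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError, RecordValidationError

YES = "yes"
NO = "no"
NA = "na"
_ANSWERS = (YES, NO, NA)

DEFAULT_CRITERIA: tuple[str, ...] = (
    "Severe negative affect with disadaptive coping",
    "Severe destructive behavior to oneself or others",
    "Multiple comorbid disorders on axis I and/or axis II due to severe psychiatric problems",
    "Severe social and societal disfunction: GAF <= threshold",
    "Severe chronic traumatisation in childhood",
    "Difficulties in developing a therapeutic relationship",
    "Treatment in specialized care was not successful",
)

GATE_QUESTION = (
    "Possibility and motivation to conform to minimal treatment conditions "
    "for psychotherapy in intensive (day)care"
)

__all__ = [
    "YES",
    "NO",
    "NA",
    "DEFAULT_CRITERIA",
    "GATE_QUESTION",
    "ToolConfig",
    "PatientRecord",
    "ToolDecision",
    "normalize_answer",
    "dichotomize_gaf",
    "score_patient",
    "score_cohort",
]


def normalize_answer(value: object) -> str:
    """Map a raw token to 'yes' / 'no' / 'na' (case-insensitive)."""
    if isinstance(value, str):
        token = value.strip().lower()
        if token in _ANSWERS:
            return token
    raise RecordValidationError(f"unknown answer token {value!r}; expected yes/no/na")


@dataclass(frozen=True)
class ToolConfig:
    """Parameters of the decision rule.

    ``na_allowed`` lists the 1-based criterion positions that may be answered
    "not applicable" (defaults: criteria 6 and 7). ``na_policy`` controls how
    NA enters the sum score: "as_no" (default) counts it as a negative answer;
    "exclude_rescale" drops the item and rescales the cut-off to the number of
    answered criteria.
    """

    criterion_names: tuple[str, ...] = DEFAULT_CRITERIA
    cutoff: int = 4
    gaf_threshold: int = 50
    na_allowed: frozenset[int] = frozenset({6, 7})
    na_policy: str = "as_no"

    def __post_init__(self) -> None:
        if len(self.criterion_names) != 7:
            raise InputError("the tool has exactly 7 criteria")
        if not (1 <= self.cutoff <= 7):
            raise InputError(f"cutoff must lie in [1, 7], got {self.cutoff}")
        if self.gaf_threshold <= 0:
            raise InputError("gaf_threshold must be a positive integer")
        if self.na_policy not in ("as_no", "exclude_rescale"):
            raise InputError(f"unknown na_policy {self.na_policy!r}")
        if not self.na_allowed <= set(range(1, 8)):
            raise InputError("na_allowed must be 1-based criterion positions")


@dataclass(frozen=True)
class PatientRecord:
    """One filled-out tool: seven criterion answers, the gate question, and
    the clinician's own referral judgement (the validation gold standard)."""

    centre_id: str
    therapist_id: str
    answers: tuple[str, ...]
    gate_q8: str
    clinical_judgement: bool

    def __post_init__(self) -> None:
        if len(self.answers) != 7:
            raise RecordValidationError(
                f"expected 7 criterion answers, got {len(self.answers)}"
            )
        object.__setattr__(
            self, "answers", tuple(normalize_answer(a) for a in self.answers)
        )
        object.__setattr__(self, "gate_q8", normalize_answer(self.gate_q8))


@dataclass(frozen=True)
class ToolDecision:
    score: int
    passed_cutoff: bool
    referral: bool
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.referral and not self.passed_cutoff:
            raise InputError("referral without passing the cut-off is impossible")


def dichotomize_gaf(gaf: int, threshold: int = 50) -> str:
    """Turn a raw 0-100 GAF rating into the criterion-4 answer:
    functioning at or below the threshold counts as YES (severe dysfunction)."""
    if not (0 <= gaf <= 100):
        raise InputError(f"GAF must lie in [0, 100], got {gaf}")
    return YES if gaf <= threshold else NO


def score_patient(record: PatientRecord, config: ToolConfig | None = None) -> ToolDecision:
    """Apply the decision rule to one record.

    Score = number of YES answers. Below the cut-off the patient is not
    referred. At or above it, the gate question decides: yes or NA refer,
    no does not.
    """
    cfg = config or ToolConfig()
    for pos, answer in enumerate(record.answers, start=1):
        if answer == NA and pos not in cfg.na_allowed:
            raise RecordValidationError(
                f"criterion {pos} ({cfg.criterion_names[pos - 1]!r}) does not allow NA"
            )
    score = sum(1 for a in record.answers if a == YES)
    if cfg.na_policy == "exclude_rescale":
        answered = sum(1 for a in record.answers if a != NA)
        effective_cutoff = math.ceil(cfg.cutoff * answered / 7) if answered else cfg.cutoff
    else:
        effective_cutoff = cfg.cutoff
    rationale = [f"score={score} (YES answers)", f"cutoff={effective_cutoff}"]
    passed = score >= effective_cutoff
    if not passed:
        rationale.append("score below cut-off -> not referred")
        return ToolDecision(score, False, False, tuple(rationale))
    rationale.append("score at or above cut-off -> gate question")
    if record.gate_q8 == NO:
        rationale.append("gate answered no -> not referred")
        referral = False
    elif record.gate_q8 == NA:
        rationale.append("gate not applicable -> referred")
        referral = True
    else:
        rationale.append("gate answered yes -> referred")
        referral = True
    return ToolDecision(score, True, referral, tuple(rationale))


def score_cohort(
    records: Sequence[PatientRecord], config: ToolConfig | None = None
) -> tuple[list[ToolDecision], pd.DataFrame]:
    """Score every record and cross-tabulate scores 0-7 by clinical judgement."""
    if not records:
        raise InputError("empty cohort")
    cfg = config or ToolConfig()
    decisions = [score_patient(r, cfg) for r in records]
    table = pd.DataFrame(
        {
            "score": [d.score for d in decisions],
            "clinical_judgement": [r.clinical_judgement for r in records],
        }
    )
    dist = (
        table.groupby(["score", "clinical_judgement"])
        .size()
        .unstack(fill_value=0)
        .reindex(range(8), fill_value=0)
        .reindex(columns=[False, True], fill_value=0)
    )
    dist.columns = ["judged_no", "judged_yes"]
    return decisions, dist
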