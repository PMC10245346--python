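"""Majority-vote aggregation of question-task answers, with early retirement.

Each subject collects up to N answers (N = the retirement limit).  The
consensus is the modal choice; a subject can be retired early once the
leading choice's margin over the runner-up exceeds the number of votes still
outstanding, because then no completion of the vote can change the winner —
e.g. with a retirement limit of five, three identical answers already decide
the outcome and the final two classifications cannot alter it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .export_parser import Answer, Classification

__all__ = [
    "QuestionConsensus",
    "RetirementRule",
    "majority_vote",
    "can_retire_early",
    "earliest_guaranteed_retirement",
    "aggregate_question_table",
]


@dataclass(frozen=True)
class QuestionConsensus:
    subject_id: str
    task_id: str
    winning_choice: str
    vote_counts: dict
    n_votes: int
    agreement_fraction: float
    tie: bool


@dataclass(frozen=True)
class RetirementRule:
    retirement_limit: int
    early_enabled: bool = True

    def __post_init__(self) -> None:
        if self.retirement_limit < 1:
            raise ValueError("retirement limit must be >= 1")


def majority_vote(answers: Sequence[str], subject_id: str = "", task_id: str = "") -> QuestionConsensus:
    """Modal choice with deterministic lexicographic tie-break (tie flagged)."""
    if not answers:
        raise ValueError("majority_vote needs at least one answer")
    counts = Counter(answers)
    top = max(counts.values())
    winners = sorted(c for c, n in counts.items() if n == top)
    return QuestionConsensus(
        subject_id=subject_id,
        task_id=task_id,
        winning_choice=winners[0],
        vote_counts=dict(counts),
        n_votes=len(answers),
        agreement_fraction=top / len(answers),
        tie=len(winners) > 1,
    )


def can_retire_early(votes_so_far: Sequence[str], rule: RetirementRule) -> bool:
    """True iff no completion to N votes can change the modal choice.

    Criterion: (top count − second count) > votes outstanding.  This is the
    weakest condition that still guarantees the outcome is fixed, for any
    number of answer choices.
    """
    n_cast = len(votes_so_far)
    if n_cast > rule.retirement_limit:
        raise ValueError(f"{n_cast} votes exceed retirement limit {rule.retirement_limit}")
    if not votes_so_far:
        return False
    counts = Counter(votes_so_far).most_common()
    top = counts[0][1]
    second = counts[1][1] if len(counts) > 1 else 0
    remaining = rule.retirement_limit - n_cast
    return (top - second) > remaining


def earliest_guaranteed_retirement(retirement_limit: int, n_choices: int = 2) -> int:
    """Smallest count of identical opening votes that guarantees early retirement.

    For unanimous votes this is floor(N/2) + 1; computed by scanning the
    retirement criterion rather than asserting the closed form.
    """
    if retirement_limit < 1:
        raise ValueError("retirement limit must be >= 1")
    if n_choices < 2:
        raise ValueError("need at least 2 answer choices")
    rule = RetirementRule(retirement_limit)
    for k in range(1, retirement_limit + 1):
        if can_retire_early(["A"] * k, rule):
            return k
    return retirement_limit  # pragma: no cover - unreachable: unanimity at N always retires


def aggregate_question_table(
    classifications: Sequence[Classification],
    task_id: str,
    rule: RetirementRule,
) -> pd.DataFrame:
    """One consensus row per subject with votes on ``task_id``.

    Classifications are assumed parsed and contributor-deduplicated.  Votes
    are ordered by created_at (ties by classification_id); a subject is
    flagged ``retired_early`` when some vote prefix already satisfied the
    early-retirement criterion.  Subjects with no votes on the task are
    omitted.
    """
    by_subject: dict[str, list[tuple[pd.Timestamp, str, str]]] = {}
    for c in classifications:
        for ann in c.annotations:
            if isinstance(ann, Answer) and ann.task_id == task_id:
                by_subject.setdefault(c.subject_id, []).append(
                    (pd.Timestamp(c.created_at), c.classification_id, ann.choice)
                )
    records = []
    for subject_id in sorted(by_subject):
        votes = [choice for _, _, choice in sorted(by_subject[subject_id])]
        votes = votes[: rule.retirement_limit]
        consensus = majority_vote(votes, subject_id=subject_id, task_id=task_id)
        retired_early = rule.early_enabled and any(
            can_retire_early(votes[:k], rule) for k in range(1, len(votes) + 1)
        )
        records.append(
            {
                "subject_id": subject_id,
                "task_id": task_id,
                "winning_choice": consensus.winning_choice,
                "n_votes": consensus.n_votes,
                "agreement_fraction": consensus.agreement_fraction,
                "tie": consensus.tie,
                "retired_early": retired_early,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "subject_id",
            "task_id",
            "winning_choice",
            "n_votes",
            "agreement_fraction",
            "tie",
            "retired_early",
        ],
    )
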