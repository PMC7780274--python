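"""Task structure of the Modified Wisconsin Card Sorting Test (M-WCST).

The M-WCST as modelled here is administered with an unannounced, fixed
rule order (color, shape, number, repeated once) over at most 48 trials.
A category is completed by six consecutive correct sorts, after which the
sorting rule silently advances.  Because the response cards of the M-WCST
are unambiguous, every card placement maps to exactly one sorting
dimension (or to none of them), so responses are modelled at the
dimension level rather than the card level.

Given a patient's ordered responses, :func:`adjudicate` deterministically
replays the task to recover the active rule, the examiner feedback and
the category-completion structure for every trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

DIMENSIONS = ("color", "shape", "number")
#: Legal values of a response: one sorting dimension, or a placement that
#: matches no attribute of any stimulus card.
RESPONSE_VALUES = DIMENSIONS + ("none",)

DEFAULT_RULE_SEQUENCE = ("color", "shape", "number", "color", "shape", "number")


class AdjudicationError(ValueError):
    """Raised when raw trial records cannot be replayed through the task."""


@dataclass(frozen=True)
class TaskConfig:
    """Administration parameters of the card-sorting task.

    Parameters
    ----------
    rule_sequence:
        Ordered sorting rules.  When more categories are completed than
        the sequence holds, it cycles from the start.
    run_length_for_category:
        Number of consecutive correct sorts that completes a category.
    max_trials:
        Maximum number of administered trials.
    """

    rule_sequence: tuple[str, ...] = DEFAULT_RULE_SEQUENCE
    run_length_for_category: int = 6
    max_trials: int = 48

    def __post_init__(self) -> None:
        if not self.rule_sequence:
            raise ValueError("rule_sequence must be non-empty")
        for rule in self.rule_sequence:
            if rule not in DIMENSIONS:
                raise ValueError(f"unknown rule {rule!r}")
        if self.run_length_for_category < 1:
            raise ValueError("run_length_for_category must be positive")
        if self.max_trials < 1:
            raise ValueError("max_trials must be positive")

    def rule_at(self, n_completed: int) -> str:
        """Active rule after ``n_completed`` completed categories (cycling)."""
        return self.rule_sequence[n_completed % len(self.rule_sequence)]


@dataclass(frozen=True)
class TrialRecord:
    """One administered trial as digitised from a record table."""

    patient_id: str
    trial_index: int  # 1-based
    response_dim: str
    feedback: bool | None = None  # optionally recorded; None if absent

    def __post_init__(self) -> None:
        if self.response_dim not in RESPONSE_VALUES:
            raise AdjudicationError(
                f"unknown response_dim {self.response_dim!r} at trial "
                f"{self.trial_index} of patient {self.patient_id}"
            )


@dataclass(frozen=True)
class AdjudicatedTrial:
    """A trial enriched with replayed rule state and feedback.

    ``run_position`` is the length of the current run of consecutive
    correct sorts *after* this trial (it resets to 0 on an error and on a
    category completion).
    """

    patient_id: str
    trial_index: int
    response_dim: str
    active_rule: str
    feedback: bool
    category_completed: bool
    run_position: int


def _check_contiguous(records: Sequence[TrialRecord], config: TaskConfig) -> None:
    if not records:
        raise AdjudicationError("empty record sequence")
    if len(records) > config.max_trials:
        raise AdjudicationError(
            f"{len(records)} trials exceed max_trials={config.max_trials}"
        )
    for pos, rec in enumerate(records, start=1):
        if rec.trial_index != pos:
            raise AdjudicationError(
                f"non-contiguous trial indices for patient "
                f"{records[0].patient_id}: expected {pos}, got {rec.trial_index}"
            )


def adjudicate(
    records: Sequence[TrialRecord], config: TaskConfig | None = None
) -> list[AdjudicatedTrial]:
    """Replay one patient's responses through the task state machine.

    Feedback is positive iff the response matches the active rule.  The
    consecutive-correct counter resets on any negative feedback and on a
    category completion, so credited runs never span two categories.  The
    rule advances (cycling the sequence) on the trial after a completion.
    """
    config = config or TaskConfig()
    _check_contiguous(records, config)

    out: list[AdjudicatedTrial] = []
    n_completed = 0
    run = 0
    for rec in records:
        rule = config.rule_at(n_completed)
        correct = rec.response_dim == rule
        run = run + 1 if correct else 0
        completed = run == config.run_length_for_category
        out.append(
            AdjudicatedTrial(
                patient_id=rec.patient_id,
                trial_index=rec.trial_index,
                response_dim=rec.response_dim,
                active_rule=rule,
                feedback=correct,
                category_completed=completed,
                run_position=0 if completed else run,
            )
        )
        if completed:
            n_completed += 1
            run = 0
    return out


def validate_feedback(
    records: Sequence[TrialRecord], config: TaskConfig | None = None
) -> list[int]:
    """Compare recorded feedback with the deterministic replay.

    Returns the (1-based) trial indices at which the recorded feedback
    column disagrees with the feedback implied by the task rules; an
    empty list means the digitised record is internally consistent.
    Records without a feedback entry are skipped.
    """
    replayed = adjudicate(records, config)
    mismatches = []
    for rec, adj in zip(records, replayed):
        if rec.feedback is not None and bool(rec.feedback) != adj.feedback:
            mismatches.append(rec.trial_index)
    return mismatches
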