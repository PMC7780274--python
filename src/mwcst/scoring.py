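"""Trial-level scoring of the four basic M-WCST performance measures.

Four measures are scored from the adjudicated trial stream:

``n_corr``
    number of correct sorts (positive-feedback trials);
``n_cat``
    number of completed categories, spread over trials as a credit of
    1/6 on each of the six trials forming a completed run, so that the
    category score of any subset of trials is well defined;
``n_PE``
    perseverative errors — failures to shift cognitive set: the previous
    trial drew negative feedback and the patient repeats the same
    response dimension;
``n_SE``
    set-loss errors — failures to maintain cognitive set: the previous
    trial drew positive feedback, the patient abandons the previous
    dimension, and the new placement is wrong.

Each trial after the first is an opportunity for exactly one error type,
determined by the preceding feedback (``poss_pe`` after negative,
``poss_se`` after positive feedback).  Trial 1 has no preceding feedback
and is an opportunity for neither.

The per-trial indicator columns are the splittable substrate of the
reliability analysis: every measure over a subset of trials is the sum
of its column over that subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .task_model import AdjudicatedTrial, TaskConfig, TrialRecord, adjudicate

BASIC_MEASURES = ("n_corr", "n_cat", "n_PE", "n_SE")
#: score-table column backing each measure
MEASURE_COLUMNS = {
    "n_corr": "correct",
    "n_cat": "cat_credit",
    "n_PE": "pe",
    "n_SE": "se",
    "n_poss_PE": "poss_pe",
    "n_poss_SE": "poss_se",
}

SCORE_COLUMNS = ("correct", "cat_credit", "pe", "se", "poss_pe", "poss_se")


@dataclass(frozen=True)
class MeasureValues:
    """Aggregated measure values over a set of trials."""

    n_corr: float
    n_cat: float
    n_PE: float
    n_SE: float
    n_poss_PE: float
    n_poss_SE: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_corr": self.n_corr,
            "n_cat": self.n_cat,
            "n_PE": self.n_PE,
            "n_SE": self.n_SE,
            "n_poss_PE": self.n_poss_PE,
            "n_poss_SE": self.n_poss_SE,
        }


def score_patient(trials: Sequence[AdjudicatedTrial]) -> pd.DataFrame:
    """Per-trial score vectors for one patient.

    Returns a DataFrame indexed by 1-based trial number with columns
    ``correct, cat_credit, pe, se, poss_pe, poss_se``.
    """
    n = len(trials)
    correct = np.array([t.feedback for t in trials], dtype=float)
    resp = [t.response_dim for t in trials]

    cat_credit = np.zeros(n)
    run_len = _infer_run_length(trials)
    for i, t in enumerate(trials):
        if t.category_completed:
            cat_credit[i - run_len + 1 : i + 1] = 1.0 / run_len

    poss_pe = np.zeros(n)
    poss_se = np.zeros(n)
    pe = np.zeros(n)
    se = np.zeros(n)
    for i in range(1, n):
        prev_pos = trials[i - 1].feedback
        if prev_pos:
            poss_se[i] = 1.0
            if resp[i] != resp[i - 1] and not trials[i].feedback:
                se[i] = 1.0
        else:
            poss_pe[i] = 1.0
            if resp[i] == resp[i - 1]:
                pe[i] = 1.0

    return pd.DataFrame(
        {
            "correct": correct,
            "cat_credit": cat_credit,
            "pe": pe,
            "se": se,
            "poss_pe": poss_pe,
            "poss_se": poss_se,
        },
        index=pd.RangeIndex(1, n + 1, name="trial"),
    )


def _infer_run_length(trials: Sequence[AdjudicatedTrial]) -> int:
    # Completed runs are the trials from the last reset to the completion
    # trial; under adjudication this span always has the configured
    # category length, recoverable from the first completion's position.
    for i, t in enumerate(trials):
        if t.category_completed:
            j = i
            while j > 0 and trials[j - 1].feedback and not trials[j - 1].category_completed:
                j -= 1
            return i - j + 1
    return 6  # no completion: value is unused (no credit assigned)


def aggregate(scores: pd.DataFrame, subset: Iterable[int] | None = None) -> MeasureValues:
    """Sum the per-trial score columns over a subset of trial numbers.

    ``subset=None`` aggregates all administered trials.  Aggregation is
    additive over disjoint subsets by construction.
    """
    if subset is None:
        sub = scores
    else:
        idx = pd.Index(sorted(set(subset)))
        missing = idx.difference(scores.index)
        if len(missing):
            raise IndexError(f"trial indices not administered: {list(missing)}")
        sub = scores.loc[idx]
    return MeasureValues(
        n_corr=float(sub["correct"].sum()),
        n_cat=float(sub["cat_credit"].sum()),
        n_PE=float(sub["pe"].sum()),
        n_SE=float(sub["se"].sum()),
        n_poss_PE=float(sub["poss_pe"].sum()),
        n_poss_SE=float(sub["poss_se"].sum()),
    )


def filter_completion(
    cohort: Mapping[str, Sequence[TrialRecord]], min_trials: int
) -> list[str]:
    """Patients who completed at least ``min_trials`` trials.

    The downstream analyses then use exactly the first ``min_trials``
    trials of each included patient.  ``min_trials`` is 48 for the
    complete-test analysis and 24 for the first-half analysis.
    """
    return [pid for pid, recs in cohort.items() if len(recs) >= min_trials]


def score_cohort(
    cohort: Mapping[str, Sequence[TrialRecord]],
    n_trials: int,
    config: TaskConfig | None = None,
) -> "CohortScores":
    """Adjudicate and score all patients with >= ``n_trials`` trials.

    Each included patient contributes exactly the first ``n_trials``
    trials; shorter records are excluded (the completion filter).
    """
    config = config or TaskConfig()
    included = filter_completion(cohort, n_trials)
    tables = {}
    for pid in included:
        adj = adjudicate(list(cohort[pid])[:n_trials], config)
        tables[pid] = score_patient(adj)
    return CohortScores(tables=tables, n_trials=n_trials)


@dataclass
class CohortScores:
    """Stacked per-trial score tables for an analysis sample.

    ``matrix(col)`` exposes a patients x trials array for one score
    column — the shape consumed by the split-half engine.
    """

    tables: dict[str, pd.DataFrame]
    n_trials: int

    @property
    def patient_ids(self) -> list[str]:
        return list(self.tables)

    @property
    def n_patients(self) -> int:
        return len(self.tables)

    def matrix(self, column: str) -> np.ndarray:
        if column not in SCORE_COLUMNS:
            raise KeyError(f"unknown score column {column!r}")
        return np.vstack([t[column].to_numpy() for t in self.tables.values()])

    def measure_matrix(self, measure: str) -> np.ndarray:
        return self.matrix(MEASURE_COLUMNS[measure])

    def summary(self) -> pd.DataFrame:
        """Per-patient totals of all six measures (descriptives table)."""
        rows = {pid: aggregate(t).as_dict() for pid, t in self.tables.items()}
        out = pd.DataFrame.from_dict(rows, orient="index")
        out.index.name = "patient_id"
        return out
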