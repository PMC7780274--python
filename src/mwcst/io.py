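"""CSV input/output and the end-to-end analysis pipeline.

The raw input is one CSV row per administered trial with columns
``patient_id, trial, response`` (and optionally ``feedback`` as 0/1).
``run_pipeline`` ties the stages together: completion filter ->
adjudication and scoring -> descriptives -> coefficient alpha ->
systematic and random-split reliability grid, writing CSV tables plus a
JSON result object that records the seed and iteration count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import composites, reliability
from .scoring import CohortScores, score_cohort
from .split_engine import valid_grains
from .task_model import RESPONSE_VALUES, TaskConfig, TrialRecord, validate_feedback

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("patient_id", "trial", "response")


def _package_version() -> str:
    try:
        return version("mwcst")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


class RecordFormatError(ValueError):
    """The trial-record CSV violates the input contract."""


def read_records(path: str | Path) -> dict[str, list[TrialRecord]]:
    """Read and validate a trial-record CSV.

    Returns records grouped by patient (in order of first appearance)
    and ordered by trial index within patient.  Duplicate or
    non-contiguous trial indices raise errors naming the offending rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RecordFormatError(f"{path}: missing required columns {missing}")
    has_feedback = "feedback" in df.columns

    bad = ~df["response"].isin(RESPONSE_VALUES)
    if bad.any():
        row = int(df.index[bad][0]) + 2  # header + 1-based
        raise RecordFormatError(
            f"{path}: invalid response {df.loc[bad, 'response'].iloc[0]!r} at row {row}"
        )

    cohort: dict[str, list[TrialRecord]] = {}
    for pid, group in df.groupby("patient_id", sort=False):
        group = group.sort_values("trial")
        trials = group["trial"].to_numpy()
        dup = group.index[pd.Series(trials).duplicated().to_numpy()]
        if len(dup):
            raise RecordFormatError(
                f"{path}: duplicate (patient, trial) at row {int(dup[0]) + 2} "
                f"(patient {pid})"
            )
        expected = np.arange(1, len(trials) + 1)
        if not np.array_equal(trials, expected):
            off = int(np.argmax(trials != expected))
            raise RecordFormatError(
                f"{path}: non-contiguous trial indices for patient {pid} at row "
                f"{int(group.index[off]) + 2} (expected trial {off + 1}, "
                f"got {int(trials[off])})"
            )
        cohort[str(pid)] = [
            TrialRecord(
                patient_id=str(pid),
                trial_index=int(r.trial),
                response_dim=str(r.response),
                feedback=(bool(int(r.feedback)) if has_feedback and pd.notna(r.feedback) else None),
            )
            for r in group.itertuples()
        ]
    return cohort


def write_records(cohort: Mapping[str, Sequence[TrialRecord]], path: str | Path) -> None:
    """Write a cohort back to the trial-record CSV format."""
    rows = []
    any_feedback = any(
        rec.feedback is not None for recs in cohort.values() for rec in recs
    )
    for pid, recs in cohort.items():
        for rec in recs:
            row = {"patient_id": pid, "trial": rec.trial_index, "response": rec.response_dim}
            if any_feedback:
                row["feedback"] = int(rec.feedback) if rec.feedback is not None else ""
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input_path: str | Path
    variant: str = "complete-48"  # or "first-half-24"
    n_iterations: int = 100_000
    seed: int = 0
    grains: list[int] | None = None  # None -> all valid for the variant
    output_dir: str | Path = "results"

    def __post_init__(self) -> None:
        if self.variant not in ("complete-48", "first-half-24"):
            raise ValueError("variant must be 'complete-48' or 'first-half-24'")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @property
    def n_trials(self) -> int:
        return 48 if self.variant == "complete-48" else 24


def _write_grid_csv(grid: pd.DataFrame, path: Path) -> None:
    # coefficients to 3 decimals, structural gaps rendered "na"
    grid.round(3).to_csv(path, na_rep="na")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full reliability analysis and write its outputs.

    Returns the result bundle: descriptives, alpha table, reliability
    grid, and provenance (seed, iteration count, exclusions).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = read_records(config.input_path)
    n_with_feedback = sum(
        1 for recs in cohort.values() if any(r.feedback is not None for r in recs)
    )
    if n_with_feedback:
        for pid, recs in cohort.items():
            mismatches = validate_feedback(recs)
            if mismatches:
                raise RecordFormatError(
                    f"recorded feedback inconsistent with task replay for patient "
                    f"{pid} at trials {mismatches}"
                )

    scores = score_cohort(cohort, config.n_trials)
    if scores.n_patients < 3:
        raise ValueError(
            f"only {scores.n_patients} patients completed {config.n_trials} trials"
        )
    logger.info(
        "included %d of %d patients at min_trials=%d",
        scores.n_patients,
        len(cohort),
        config.n_trials,
    )

    summary = scores.summary()
    descriptives = summary.agg(["mean", "std"]).T
    alpha = composites.alpha_table(summary)

    grains = config.grains if config.grains is not None else valid_grains(config.n_trials)
    grid = reliability.systematic_table(
        scores,
        grains=grains,
        n_iterations=config.n_iterations,
        seed=config.seed,
    )

    # per-trial score table, long format
    score_rows = []
    for pid, table in scores.tables.items():
        t = table.reset_index()
        t.insert(0, "patient_id", pid)
        score_rows.append(t)
    score_table = pd.concat(score_rows, ignore_index=True)

    provenance = {
        "seed": config.seed,
        "n_iterations": config.n_iterations,
        "variant": config.variant,
        "n_trials": config.n_trials,
        "n_patients_included": scores.n_patients,
        "n_patients_input": len(cohort),
        "grains": list(grains),
        "version": _package_version(),
    }

    score_table.to_csv(outdir / "trial_scores.csv", index=False)
    summary.to_csv(outdir / "patient_summary.csv")
    descriptives.to_csv(outdir / "descriptives.csv")
    alpha.round(3).to_csv(outdir / "alpha.csv")
    _write_grid_csv(grid, outdir / "reliability_grid.csv")

    result = {
        "provenance": provenance,
        "descriptives": {
            m: {"mean": float(descriptives.loc[m, "mean"]), "sd": float(descriptives.loc[m, "std"])}
            for m in descriptives.index
        },
        "alpha": {k: float(v) for k, v in alpha["alpha"].items()},
        "reliability": {
            measure: {
                col: (None if pd.isna(val) else float(val))
                for col, val in row.items()
            }
            for measure, row in grid.iterrows()
        },
    }
    with open(outdir / "results.json", "w", encoding="utf-8") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    return result
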