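"""Standardized composite scores and coefficient alpha.

Composite M-WCST indices are built from the four basic measures by
z-standardizing each measure across patients on a given set of trials
(z = (x - M) / SD, sample SD) and summing the standardized scores with
signs aligned to task success: correct sorts and categories enter with
+1, perseverative and set-loss errors with -1 (fewer errors mean better
performance).  The combination of categories and perseverative errors
approximates the Executive Function Composite of the M-WCST manual.

Internal consistency of a member subset is summarized by standardized
coefficient alpha, computed from the mean pairwise correlation of the
sign-aligned standardized scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import BASIC_MEASURES

#: sign with which each basic measure enters a composite
MEASURE_SIGNS = {"n_corr": 1.0, "n_cat": 1.0, "n_PE": -1.0, "n_SE": -1.0}

#: the 11 composite member sets, in canonical reporting order
COMPOSITE_MEMBER_SETS: tuple[tuple[str, ...], ...] = (
    ("n_PE", "n_SE"),
    ("n_corr", "n_cat"),
    ("n_corr", "n_PE"),
    ("n_corr", "n_SE"),
    ("n_corr", "n_PE", "n_SE"),
    ("n_cat", "n_PE"),
    ("n_cat", "n_SE"),
    ("n_cat", "n_PE", "n_SE"),
    ("n_corr", "n_cat", "n_PE"),
    ("n_corr", "n_cat", "n_SE"),
    ("n_corr", "n_cat", "n_PE", "n_SE"),
)


class DegenerateVarianceError(ValueError):
    """A measure has zero variance across patients on this trial set."""


@dataclass(frozen=True)
class CompositeSpec:
    """A signed linear combination of basic measures."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate members")
        for m in self.members:
            if m not in BASIC_MEASURES:
                raise ValueError(f"unknown measure {m!r}")

    @property
    def signs(self) -> np.ndarray:
        return np.array([MEASURE_SIGNS[m] for m in self.members])

    @property
    def name(self) -> str:
        return " + ".join(self.members)


def default_composites() -> list[CompositeSpec]:
    """The 11 composite specifications in reporting order."""
    return [CompositeSpec(members=m) for m in COMPOSITE_MEMBER_SETS]


def all_measure_specs() -> list[CompositeSpec]:
    """The 4 basic measures (as singleton specs) followed by the 11
    composites — the 15 rows of the reliability tables."""
    singles = [CompositeSpec(members=(m,)) for m in BASIC_MEASURES]
    return singles + default_composites()


def z_transform(values: np.ndarray) -> np.ndarray:
    """Standardize per-patient values across the sample (sample SD).

    Raises :class:`DegenerateVarianceError` when the SD is zero: a
    constant measure carries no between-patient information and cannot
    be standardized.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector of at least 2 patients")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateVarianceError("zero variance across patients")
    return (x - x.mean()) / sd


def composite(z_scores: dict[str, np.ndarray], spec: CompositeSpec) -> np.ndarray:
    """Signed sum of member z-scores, per patient.

    All members must be standardized on the same trial set and sample.
    """
    missing = [m for m in spec.members if m not in z_scores]
    if missing:
        raise KeyError(f"missing standardized members: {missing}")
    lengths = {len(z_scores[m]) for m in spec.members}
    if len(lengths) != 1:
        raise ValueError("member z-score vectors differ in length")
    out = np.zeros(lengths.pop())
    for m in spec.members:
        out += MEASURE_SIGNS[m] * np.asarray(z_scores[m], dtype=float)
    return out


def cronbach_alpha(scores: np.ndarray) -> float:
    """Standardized coefficient alpha of a patients x members matrix.

    Member columns are expected sign-aligned (errors negated).  With k
    members and mean pairwise correlation r-bar,
    alpha = k r-bar / (1 + (k - 1) r-bar); for k = 2 this coincides with
    the Spearman-Brown correction of the single inter-member correlation.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-d matrix with >= 2 members")
    if x.shape[0] < 3:
        raise ValueError("need >= 3 patients")
    sds = x.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise DegenerateVarianceError("a member has zero variance")
    k = x.shape[1]
    corr = np.corrcoef(x, rowvar=False)
    r_bar = (corr.sum() - k) / (k * (k - 1))
    return float(k * r_bar / (1.0 + (k - 1) * r_bar))


def alpha_table(summary, specs: list[CompositeSpec] | None = None) -> "pd.DataFrame":
    """Coefficient alpha for each multi-member composite.

    ``summary`` is a per-patient totals DataFrame (one column per basic
    measure); rows mirror the reporting order of the composites.
    """
    import pandas as pd

    specs = specs if specs is not None else default_composites()
    rows = {}
    for spec in specs:
        if len(spec.members) < 2:
            continue
        cols = [
            MEASURE_SIGNS[m] * z_transform(summary[m].to_numpy())
            for m in spec.members
        ]
        rows[spec.name] = cronbach_alpha(np.column_stack(cols))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["alpha"])
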