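"""Split-half reliability estimation with Spearman-Brown correction.

For a given split, every patient contributes one score per half (basic
measures are summed over each half's trials; composite measures are
built by z-standardizing each member within the half across patients and
summing with signs).  The Pearson correlation r of the paired half
scores estimates the reliability of a half-length test and is projected
to full length by the Spearman-Brown formula

    r_SB = 2 r / (1 + r).

The sampling estimator repeats this over many uniformly random equal
splits and summarizes the resulting distribution of r_SB by its median
and the 95% highest-density interval (the shortest interval containing
95% of the sampled coefficients).  Iterations on which an estimate is
undefined (zero variance of a half score across patients, or r = -1)
are excluded and counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composites import CompositeSpec, MEASURE_SIGNS, all_measure_specs
from .scoring import CohortScores
from .split_engine import (
    SplitScheme,
    eligible,
    random_split_masks,
    systematic_split,
    valid_grains,
)

logger = logging.getLogger(__name__)

_CHUNK = 20_000  # iterations per vectorized block


class UndefinedEstimateError(ValueError):
    """The reliability estimate is undefined for this split (zero
    variance of a half score across patients, or r = -1)."""


def spearman_brown(r: float) -> float:
    """Project a half-test correlation to full test length.

    Defined for r in (-1, 1]; r = -1 makes the correction diverge and is
    signalled explicitly.  Values are not clamped.
    """
    if r <= -1.0:
        raise UndefinedEstimateError("Spearman-Brown undefined at r = -1")
    return 2.0 * r / (1.0 + r)


@dataclass(frozen=True)
class ReliabilityEstimate:
    r: float
    r_sb: float
    n_patients: int
    scheme: SplitScheme


@dataclass
class ReliabilityDistribution:
    """Sampled Spearman-Brown coefficients over random splits."""

    samples: np.ndarray
    median: float
    hdi_low: float
    hdi_high: float
    n_iterations: int
    seed: int
    n_excluded: int = 0


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval of the empirical sample containing ``mass``.

    Computed by sliding a window of ceil(mass * N) order statistics over
    the sorted sample and taking the narrowest window; ties go to the
    lower window.
    """
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n < 2:
        raise ValueError("need at least 2 samples for an HDI")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must be in (0, 1]")
    m = min(n, math.ceil(mass * n))
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def half_scores(
    cohort: CohortScores, spec: CompositeSpec, scheme: SplitScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient scores on the two halves of a split.

    For composites, members are z-standardized within each half's trial
    set (across patients) before the signed summation.
    """
    if scheme.n_trials != cohort.n_trials:
        raise ValueError("split covers a different trial count than the cohort")
    mask = scheme.indicator()
    sums_a = {m: cohort.measure_matrix(m) @ mask for m in spec.members}
    sums_b = {m: cohort.measure_matrix(m) @ ~mask for m in spec.members}
    if len(spec.members) == 1:
        (m,) = spec.members
        return sums_a[m], sums_b[m]
    from .composites import DegenerateVarianceError, z_transform

    try:
        a = sum(MEASURE_SIGNS[m] * z_transform(sums_a[m]) for m in spec.members)
        b = sum(MEASURE_SIGNS[m] * z_transform(sums_b[m]) for m in spec.members)
    except DegenerateVarianceError as exc:
        raise UndefinedEstimateError(str(exc)) from exc
    return np.asarray(a), np.asarray(b)


def split_half(
    cohort: CohortScores, spec: CompositeSpec, scheme: SplitScheme
) -> ReliabilityEstimate:
    """Reliability estimate for one measure under one split."""
    a, b = half_scores(cohort, spec, scheme)
    if len(a) < 3:
        raise ValueError("need at least 3 patients")
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    if sa == 0 or sb == 0:
        raise UndefinedEstimateError("zero variance of a half score")
    r = float(np.corrcoef(a, b)[0, 1])
    return ReliabilityEstimate(
        r=r, r_sb=spearman_brown(r), n_patients=len(a), scheme=scheme
    )


def _column_pearson(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r per column of two (patients x iterations) arrays.

    Returns (r, valid) where invalid columns have a zero denominator.
    """
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = (ac * bc).sum(axis=0)
    den = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    valid = den > 0
    r = np.full(a.shape[1], np.nan)
    np.divide(num, den, out=r, where=valid)
    return r, valid


def _column_z(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = x.std(axis=0, ddof=1)
    valid = sd > 0
    z = np.zeros_like(x, dtype=float)
    np.divide(x - x.mean(axis=0), sd, out=z, where=valid)
    return z, valid


def _sample_rsb_chunk(
    cohort: CohortScores, spec: CompositeSpec, masks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """r_SB per random split mask (rows of ``masks``); vectorized."""
    mt = masks.T.astype(float)
    a_sums = {m: cohort.measure_matrix(m) @ mt for m in spec.members}
    b_sums = {m: cohort.measure_matrix(m) @ (1.0 - mt) for m in spec.members}
    valid = np.ones(masks.shape[0], dtype=bool)
    if len(spec.members) == 1:
        (m,) = spec.members
        a, b = a_sums[m], b_sums[m]
    else:
        a = np.zeros_like(a_sums[spec.members[0]])
        b = np.zeros_like(a)
        for m in spec.members:
            za, va = _column_z(a_sums[m])
            zb, vb = _column_z(b_sums[m])
            a += MEASURE_SIGNS[m] * za
            b += MEASURE_SIGNS[m] * zb
            valid &= va & vb
    r, v = _column_pearson(a, b)
    valid &= v & (r > -1.0)
    rsb = np.full(r.shape, np.nan)
    np.divide(2.0 * r, 1.0 + r, out=rsb, where=valid)
    return rsb, valid


def sample_distribution(
    cohort: CohortScores,
    spec: CompositeSpec,
    n_iterations: int = 100_000,
    seed: int = 0,
) -> ReliabilityDistribution:
    """Sampling distribution of r_SB over uniformly random splits.

    Fully reproducible for a given seed.  Undefined iterations are
    excluded from the summary and counted in ``n_excluded``; a fatal
    error is raised if every iteration is undefined.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    kept: list[np.ndarray] = []
    n_excluded = 0
    done = 0
    while done < n_iterations:
        size = min(_CHUNK, n_iterations - done)
        masks = random_split_masks(cohort.n_trials, size, rng)
        rsb, valid = _sample_rsb_chunk(cohort, spec, masks)
        kept.append(rsb[valid])
        n_excluded += int((~valid).sum())
        done += size
    samples = np.concatenate(kept)
    if samples.size == 0:
        raise UndefinedEstimateError(
            f"all {n_iterations} iterations undefined for {spec.name}"
        )
    if n_excluded > 0.01 * n_iterations:
        logger.warning(
            "%s: %d of %d iterations undefined and excluded",
            spec.name,
            n_excluded,
            n_iterations,
        )
    low, high = hdi(samples) if samples.size > 1 else (samples[0], samples[0])
    return ReliabilityDistribution(
        samples=samples,
        median=float(np.median(samples)),
        hdi_low=float(low),
        hdi_high=float(high),
        n_iterations=n_iterations,
        seed=seed,
        n_excluded=n_excluded,
    )


def systematic_table(
    cohort: CohortScores,
    specs: list[CompositeSpec] | None = None,
    grains: list[int] | None = None,
    n_iterations: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid of r_SB: one row per measure, one column per grain size,
    plus median and 95% HDI of the random-split distribution.

    Structurally ineligible (measure, grain) cells hold NaN and are
    rendered "na" on CSV export.
    """
    specs = specs if specs is not None else all_measure_specs()
    grains = grains if grains is not None else valid_grains(cohort.n_trials)
    rows = {}
    for spec in specs:
        row = {}
        for g in grains:
            if not eligible(spec.members, g):
                row[f"grain_{g}"] = np.nan
                continue
            est = split_half(cohort, spec, systematic_split(cohort.n_trials, g))
            row[f"grain_{g}"] = est.r_sb
        dist = sample_distribution(cohort, spec, n_iterations=n_iterations, seed=seed)
        row["random_median"] = dist.median
        row["hdi_low"] = dist.hdi_low
        row["hdi_high"] = dist.hdi_high
        rows[spec.name] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "measure"
    return out
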