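"""Split-half estimation, Spearman-Brown correction, HDI, sampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mwcst.composites import CompositeSpec, MEASURE_SIGNS, z_transform
from mwcst.reliability import (
    UndefinedEstimateError,
    hdi,
    half_scores,
    sample_distribution,
    spearman_brown,
    split_half,
    systematic_table,
)
from mwcst.scoring import CohortScores
from mwcst.split_engine import eligible, systematic_split, valid_grains
from mwcst.synthetic import bernoulli_cohort


def table_cohort(matrix):
    """CohortScores whose only informative column is per-trial success."""
    matrix = np.asarray(matrix, dtype=float)
    n_trials = matrix.shape[1]
    tables = {}
    for j, row in enumerate(matrix):
        df = pd.DataFrame(
            0.0,
            index=pd.RangeIndex(1, n_trials + 1, name="trial"),
            columns=["correct", "cat_credit", "pe", "se", "poss_pe", "poss_se"],
        )
        df["correct"] = row
        tables[f"p{j}"] = df
    return CohortScores(tables=tables, n_trials=n_trials)


N_CORR = CompositeSpec(("n_corr",))


@pytest.mark.parametrize("r, expected", [(1.0, 1.0), (0.0, 0.0), (0.5, 2 / 3)])
def test_spearman_brown_values(r, expected):
    assert spearman_brown(r) == pytest.approx(expected)


def test_spearman_brown_undefined_at_minus_one_and_monotone():
    with pytest.raises(UndefinedEstimateError):
        spearman_brown(-1.0)
    rs = np.linspace(-0.99, 1.0, 100)
    vals = [spearman_brown(r) for r in rs]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert vals[0] < -1  # no clamping of negative coefficients


def test_identical_halves_give_perfect_reliability():
    rng = np.random.default_rng(0)
    row_vals = rng.random(6)
    # every trial of a patient carries the same value: all halves agree
    cohort = table_cohort(np.tile(row_vals[:, None], (1, 8)))
    est = split_half(cohort, N_CORR, systematic_split(8, 1))
    assert est.r == pytest.approx(1.0)
    assert est.r_sb == pytest.approx(1.0)


def test_pearson_matches_textbook_formula_on_toy_cohort():
    # five patients; compare against an independent implementation
    matrix = np.array(
        [
            [1, 0, 1, 1, 0, 1],
            [0, 0, 1, 0, 0, 0],
            [1, 1, 1, 1, 1, 1],
            [0, 1, 0, 1, 1, 0],
            [1, 0, 0, 0, 1, 1],
        ],
        dtype=float,
    )
    cohort = table_cohort(matrix)
    scheme = systematic_split(6, 1)
    mask = scheme.indicator()
    a, b = matrix @ mask, matrix @ ~mask
    expected_r = stats.pearsonr(a, b).statistic
    est = split_half(cohort, N_CORR, scheme)
    assert est.r == pytest.approx(expected_r)
    assert est.r_sb == pytest.approx(2 * expected_r / (1 + expected_r))


def test_estimate_invariant_under_joint_patient_permutation():
    rng = np.random.default_rng(1)
    matrix = rng.random((10, 8))
    scheme = systematic_split(8, 2)
    est = split_half(table_cohort(matrix), N_CORR, scheme)
    perm = rng.permutation(10)
    est_p = split_half(table_cohort(matrix[perm]), N_CORR, scheme)
    assert est_p.r == pytest.approx(est.r)


def test_zero_variance_half_signals_undefined():
    cohort = table_cohort(np.ones((5, 6)))
    with pytest.raises(UndefinedEstimateError):
        split_half(cohort, N_CORR, systematic_split(6, 1))


def test_composite_halves_are_standardized_within_half(sim_scores):
    spec = CompositeSpec(("n_cat", "n_PE"))
    scheme = systematic_split(48, 4)
    a, b = half_scores(sim_scores, spec, scheme)
    mask = scheme.indicator()
    for half, got in ((mask, a), (~mask, b)):
        expected = np.zeros(sim_scores.n_patients)
        for m in spec.members:
            expected += MEASURE_SIGNS[m] * z_transform(
                sim_scores.measure_matrix(m) @ half
            )
        assert got == pytest.approx(expected)
        assert got.mean() == pytest.approx(0.0, abs=1e-10)


def test_hdi_evenly_spaced_and_degenerate_samples():
    samples = np.linspace(0.0, 1.0, 101)
    low, high = hdi(samples)
    # window of 96 of the 101 evenly spaced points, width ~0.95
    assert high - low == pytest.approx(0.95)
    assert ((samples >= low) & (samples <= high)).sum() == 96
    assert hdi(np.full(10, 0.4)) == (0.4, 0.4)
    with pytest.raises(ValueError):
        hdi([0.5])


def test_hdi_matches_brute_force_window_search():
    rng = np.random.default_rng(2)
    for _ in range(20):
        samples = np.sort(rng.normal(size=rng.integers(5, 60)) ** 3)
        m = int(np.ceil(0.95 * samples.size))
        widths = [samples[i + m - 1] - samples[i] for i in range(samples.size - m + 1)]
        i = int(np.argmin(widths))
        assert hdi(samples) == (samples[i], samples[i + m - 1])


def test_hdi_contains_the_required_mass():
    rng = np.random.default_rng(3)
    samples = rng.beta(5, 2, size=999)
    low, high = hdi(samples)
    inside = ((samples >= low) & (samples <= high)).mean()
    assert inside >= 0.95


def test_sampling_engine_matches_exhaustive_enumeration():
    rng = np.random.default_rng(4)
    matrix = (rng.random((8, 6)) < 0.6).astype(float)
    cohort = table_cohort(matrix)

    expected = set()
    for combo in itertools.combinations(range(6), 3):
        mask = np.zeros(6, dtype=bool)
        mask[list(combo)] = True
        a, b = matrix @ mask, matrix @ ~mask
        if a.std() == 0 or b.std() == 0:
            continue
        r = stats.pearsonr(a, b).statistic
        if r > -1:
            expected.add(round(2 * r / (1 + r), 9))

    dist = sample_distribution(cohort, N_CORR, n_iterations=4000, seed=5)
    sampled = {round(v, 9) for v in dist.samples}
    assert sampled == expected


def test_sample_distribution_is_deterministic_given_seed():
    cohort = bernoulli_cohort(2, 2, 40, 12, rng=6).as_cohort_scores()
    d1 = sample_distribution(cohort, N_CORR, n_iterations=500, seed=9)
    d2 = sample_distribution(cohort, N_CORR, n_iterations=500, seed=9)
    assert np.array_equal(d1.samples, d2.samples)
    assert (d1.median, d1.hdi_low, d1.hdi_high) == (d2.median, d2.hdi_low, d2.hdi_high)


def test_degenerate_perfect_cohort_yields_unit_distribution():
    rng = np.random.default_rng(7)
    cohort = table_cohort(np.tile(rng.random(5)[:, None], (1, 8)))
    dist = sample_distribution(cohort, N_CORR, n_iterations=200, seed=8)
    assert dist.median == pytest.approx(1.0)
    assert (dist.hdi_low, dist.hdi_high) == (pytest.approx(1.0), pytest.approx(1.0))


def test_all_undefined_iterations_is_fatal():
    cohort = table_cohort(np.ones((5, 6)))
    with pytest.raises(UndefinedEstimateError):
        sample_distribution(cohort, N_CORR, n_iterations=50, seed=0)


def test_undefined_iterations_are_excluded_and_counted():
    # two aberrant patients: splits separating trials 1 and 2 stay
    # defined, those keeping them together collapse to zero variance in
    # one half and must be excluded
    matrix = np.ones((5, 4))
    matrix[0, 0] = 0.0
    matrix[1, 1] = 0.0
    dist = sample_distribution(table_cohort(matrix), N_CORR, n_iterations=300, seed=1)
    assert dist.n_excluded > 0
    assert dist.samples.size + dist.n_excluded == 300


def test_systematic_table_structure_and_composition(sim_scores):
    specs = [N_CORR, CompositeSpec(("n_cat", "n_PE"))]
    grid = systematic_table(sim_scores, specs=specs, n_iterations=200, seed=3)
    assert list(grid.columns) == [
        f"grain_{g}" for g in valid_grains(48)
    ] + ["random_median", "hdi_low", "hdi_high"]
    # single cell equals a direct split-half call
    est = split_half(sim_scores, N_CORR, systematic_split(48, 4))
    assert grid.loc["n_corr", "grain_4"] == pytest.approx(est.r_sb)
    # ineligible cells are structural gaps
    assert np.isnan(grid.loc["n_cat + n_PE", "grain_1"])
    assert np.isnan(grid.loc["n_cat + n_PE", "grain_3"])
    assert (grid.loc[:, "hdi_low"] <= grid.loc[:, "random_median"]).all()
    assert (grid.loc[:, "random_median"] <= grid.loc[:, "hdi_high"]).all()
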