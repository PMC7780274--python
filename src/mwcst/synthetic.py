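"""Synthetic patient cohorts and analytic reliability oracles.

No clinical data ship with this package.  The generator produces
cohorts with the statistical structure the reliability analysis rests
on: patients whose perseveration and set-loss propensities are stable
within the test but heterogeneous between patients.  Under classical
test theory (rel = 1 - sigma_e^2 / sigma_x^2) it is exactly this
between-patient heterogeneity, relative to trial-level noise, that sets
split-half reliability — so the generator doubles as a test bed whose
true reliability is controlled.

Behavioral agent
----------------
Each simulated patient is a first-order Markov responder: after
positive feedback the previous dimension is repeated with probability
1 - p_setloss (otherwise the patient switches to another dimension
uniformly); after negative feedback the previous dimension is repeated
with probability p_persev (a perseveration), otherwise the patient
switches uniformly among the two other dimensions.  Propensities are
drawn per patient from Beta distributions.

The default calibration (``CLINICAL_DEFAULT``) targets the descriptive
profile of a mixed neurological inpatient sample on a 48-trial
administration: roughly half of all sorts correct, about three
categories, about nine perseverative errors with an SD of similar
magnitude, and about three set-loss errors, with conditional error
probabilities near .4 (perseveration) and near .1 (set loss).  These
hyperparameters are artifact choices, not estimates from any real
sample.

Analytic oracle
---------------
:func:`bernoulli_cohort` generates the simplest cohort with a known
reliability — per-patient success rates theta_j ~ Beta(a, b) and i.i.d.
Bernoulli trials — together with the closed-form split-half reliability
of half-sums implied by the Beta moments (true-score variance of a
half-sum against binomial error variance), Spearman-Brown-corrected to
full length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .task_model import (
    DIMENSIONS,
    TaskConfig,
    TrialRecord,
)


def classical_reliability(var_total: float, var_error: float) -> float:
    """Classical test-theory reliability 1 - sigma_e^2 / sigma_x^2.

    ``var_total`` is the observed-score variance, ``var_error`` the
    error variance; e.g. (20, 10) -> 0.50 and (100, 10) -> 0.90.
    """
    if var_total <= 0:
        raise ValueError("var_total must be positive")
    if not 0 <= var_error <= var_total:
        raise ValueError("var_error must lie in [0, var_total]")
    return 1.0 - var_error / var_total


@dataclass(frozen=True)
class AgentParams:
    """Response propensities of one simulated patient."""

    p_persev: float
    p_setloss: float
    #: probability over (color, shape, number) for the first response
    initial_preference: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        for p in (self.p_persev, self.p_setloss):
            if not 0.0 <= p <= 1.0:
                raise ValueError("propensities must be probabilities")
        if abs(sum(self.initial_preference) - 1.0) > 1e-9:
            raise ValueError("initial_preference must sum to 1")


@dataclass(frozen=True)
class PopulationParams:
    """Beta hyperparameters of the between-patient propensity mixture."""

    persev_a: float
    persev_b: float
    setloss_a: float
    setloss_b: float
    n_patients: int = 128
    #: optional discrete distribution of administered-trial counts, as
    #: (lengths, probabilities); None administers max_trials to everyone
    truncation: tuple[Sequence[int], Sequence[float]] | None = None

    def __post_init__(self) -> None:
        for v in (self.persev_a, self.persev_b, self.setloss_a, self.setloss_b):
            if v <= 0:
                raise ValueError("Beta hyperparameters must be positive")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")


def _clinical_truncation() -> tuple[list[int], list[float]]:
    # Mirrors the attrition pattern of a consecutively referred inpatient
    # sample: ~12% stop early, half of those before trial 24 (lengths
    # 3-17) and half between trials 24 and 28.
    lengths = [48] + list(range(3, 18)) + list(range(24, 29))
    p_full = 128 / 146
    p_early = (9 / 146) / 15
    p_late = (9 / 146) / 5
    probs = [p_full] + [p_early] * 15 + [p_late] * 5
    return lengths, probs


#: default calibration of the heterogeneous patient population
CLINICAL_DEFAULT = PopulationParams(
    persev_a=0.75,
    persev_b=1.4,
    setloss_a=0.55,
    setloss_b=3.2,
    n_patients=128,
)


def simulate_patient(
    agent: AgentParams,
    config: TaskConfig,
    rng: np.random.Generator,
    patient_id: str = "sim",
    n_trials: int | None = None,
) -> list[TrialRecord]:
    """Simulate one patient's response stream (with generated feedback).

    The returned records carry the simulator's own feedback so that the
    round trip through task adjudication can be verified exactly.
    """
    n = n_trials if n_trials is not None else config.max_trials
    if not 1 <= n <= config.max_trials:
        raise ValueError("n_trials out of range")
    records: list[TrialRecord] = []
    n_completed = 0
    run = 0
    prev_resp: str | None = None
    prev_fb: bool | None = None
    for t in range(1, n + 1):
        if prev_resp is None:
            resp = DIMENSIONS[rng.choice(3, p=agent.initial_preference)]
        elif prev_fb:
            if rng.random() < agent.p_setloss:
                others = [d for d in DIMENSIONS if d != prev_resp]
                resp = others[rng.integers(len(others))]
            else:
                resp = prev_resp
        else:
            if rng.random() < agent.p_persev:
                resp = prev_resp
            else:
                others = [d for d in DIMENSIONS if d != prev_resp]
                resp = others[rng.integers(len(others))]
        rule = config.rule_at(n_completed)
        fb = resp == rule
        run = run + 1 if fb else 0
        if run == config.run_length_for_category:
            n_completed += 1
            run = 0
        records.append(
            TrialRecord(
                patient_id=patient_id, trial_index=t, response_dim=resp, feedback=fb
            )
        )
        prev_resp, prev_fb = resp, fb
    return records


def simulate_cohort(
    pop: PopulationParams = CLINICAL_DEFAULT,
    config: TaskConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> dict[str, list[TrialRecord]]:
    """Simulate an independent cohort of heterogeneous patients.

    Per-patient propensities are drawn from the population's Beta
    distributions; an optional truncation distribution administers
    fewer than ``max_trials`` trials to some patients.
    """
    config = config or TaskConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    persev = rng.beta(pop.persev_a, pop.persev_b, size=pop.n_patients)
    setloss = rng.beta(pop.setloss_a, pop.setloss_b, size=pop.n_patients)
    if pop.truncation is not None:
        lengths_pool, probs = pop.truncation
        lengths = rng.choice(lengths_pool, size=pop.n_patients, p=np.asarray(probs))
    else:
        lengths = np.full(pop.n_patients, config.max_trials)
    width = len(str(pop.n_patients))
    cohort = {}
    for j in range(pop.n_patients):
        pid = f"P{j + 1:0{width}d}"
        agent = AgentParams(p_persev=float(persev[j]), p_setloss=float(setloss[j]))
        cohort[pid] = simulate_patient(
            agent, config, rng, patient_id=pid, n_trials=int(lengths[j])
        )
    return cohort


def clinical_cohort_with_attrition(
    n_patients: int = 146, rng: np.random.Generator | int | None = None
) -> dict[str, list[TrialRecord]]:
    """Default-calibration cohort including early-termination patients."""
    pop = PopulationParams(
        persev_a=CLINICAL_DEFAULT.persev_a,
        persev_b=CLINICAL_DEFAULT.persev_b,
        setloss_a=CLINICAL_DEFAULT.setloss_a,
        setloss_b=CLINICAL_DEFAULT.setloss_b,
        n_patients=n_patients,
        truncation=_clinical_truncation(),
    )
    return simulate_cohort(pop, rng=rng)


@dataclass(frozen=True)
class BernoulliCohort:
    """I.i.d.-Bernoulli score table with known reliability."""

    scores: pd.DataFrame  # patients x trials, 0/1
    thetas: np.ndarray
    analytic_r_sb: float

    def as_cohort_scores(self):
        """View the 0/1 table as a scored cohort whose only informative
        column is the per-trial success indicator, so the split-half
        engine can be run on it via the ``n_corr`` measure."""
        from .scoring import CohortScores

        n_trials = self.scores.shape[1]
        tables = {}
        for pid, row in self.scores.iterrows():
            df = pd.DataFrame(
                0.0,
                index=pd.RangeIndex(1, n_trials + 1, name="trial"),
                columns=["correct", "cat_credit", "pe", "se", "poss_pe", "poss_se"],
            )
            df["correct"] = row.to_numpy()
            tables[pid] = df
        return CohortScores(tables=tables, n_trials=n_trials)


def bernoulli_split_half_reliability(a: float, b: float, n_trials: int) -> float:
    """Closed-form split-half r_SB of half-sums of Beta-Bernoulli trials.

    With theta ~ Beta(a, b) and m = n_trials / 2 i.i.d. Bernoulli(theta)
    trials per half, the correlation between two half-sums is

        rho = m Var(theta) / (m Var(theta) + E[theta (1 - theta)]),

    the true-score variance of a half-sum against its binomial error
    variance; the full-length reliability is 2 rho / (1 + rho).
    """
    if a <= 0 or b <= 0:
        raise ValueError("Beta hyperparameters must be positive")
    if n_trials % 2 != 0:
        raise ValueError("n_trials must be even")
    m = n_trials / 2
    var_theta = a * b / ((a + b) ** 2 * (a + b + 1))
    e_theta_1mtheta = a * b / ((a + b) * (a + b + 1))
    rho = m * var_theta / (m * var_theta + e_theta_1mtheta)
    return 2.0 * rho / (1.0 + rho)


def bernoulli_cohort(
    a: float,
    b: float,
    n_patients: int,
    n_trials: int,
    rng: np.random.Generator | int | None = None,
) -> BernoulliCohort:
    """Generate a Beta-Bernoulli trial table plus its analytic r_SB."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    thetas = rng.beta(a, b, size=n_patients)
    table = rng.random((n_patients, n_trials)) < thetas[:, None]
    width = len(str(n_patients))
    scores = pd.DataFrame(
        table.astype(float),
        index=[f"P{j + 1:0{width}d}" for j in range(n_patients)],
        columns=pd.RangeIndex(1, n_trials + 1, name="trial"),
    )
    return BernoulliCohort(
        scores=scores,
        thetas=thetas,
        analytic_r_sb=bernoulli_split_half_reliability(a, b, n_trials),
    )
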