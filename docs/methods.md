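# Methods

## The measurement problem

The Modified Wisconsin Card Sorting Test (M-WCST) is administered once:
48 card placements, each sorted by color, shape or number under a
prevailing rule the patient must infer from trial-by-trial feedback.
Six consecutive correct sorts complete a category and silently advance
the rule along the fixed order color → shape → number (twice).  From a
single administration, split-half reliability of a score is estimated by
dividing the trials into two halves, computing the score per half and
per patient, correlating the paired half scores across patients, and
projecting the half-length correlation r to full length with the
Spearman–Brown formula r_SB = 2r/(1 + r).

Classical test theory frames what such a coefficient means:
rel = 1 − σ²_e/σ²_x, so reliability is a joint property of the
instrument's error variance and the between-patient variance of the
sample at hand.  The package therefore treats reliability as a quantity
to be *estimated from the user's own trial-level records*, not imported
from a manual.

## Task replay and scoring

Raw input is one row per administered trial (patient, 1-based trial
index, chosen dimension; `none` marks a placement matching no stimulus
attribute).  `task_model.adjudicate` replays the deterministic task
state machine to recover feedback and rule state; if the digitised
records carry a feedback column, `validate_feedback` cross-checks it
against the replay.

Per-trial scoring rules (trial 1 is ineligible for either error type):

- **correct** — feedback positive.
- **category credit** — each trial of a completed six-trial run carries
  1/6 of a category, so the category score of *any* subset of trials is
  defined.  The run counter resets at completion, so credited runs are
  disjoint and a complete record's category total is an integer.
- **perseverative error (PE)** — previous feedback negative and the same
  dimension repeated.  This local operationalization makes the
  opportunity count n_poss_PE equal the number of post-negative trials,
  so n_poss_PE + n_poss_SE = 47 on a complete record.
- **set-loss error (SE)** — previous feedback positive, dimension
  changed, and the new placement wrong.  Conditioning on the error
  prevents a correct spontaneous switch at an unannounced rule change
  from being scored as set loss.  A consequence used as an invariant:
  SE cannot occur on consecutive trials.
- An error that *maintains* the old dimension right after a category
  completion (previous feedback positive, dimension unchanged) is
  neither PE nor SE; total errors can therefore exceed n_PE + n_SE.

Two of these choices are genuinely open given only verbal definitions:
whether PE requires repeating the immediately preceding dimension (used
here) rather than the previously reinforced rule, and whether a correct
post-completion switch counts as set loss (here it does not).  Both
choices are the ones consistent with the opportunity-count arithmetic
above.

## Composites and alpha

Basic scores on a trial set k are standardized across the analysis
sample, z = (x − M_k)/SD_k, with the sample (n−1) SD.  Error scores
enter composites with a minus sign; the 11 packaged member sets cover
all combinations of the four basic measures with at least two members.
The categories + perseverative-errors composite approximates the
M-WCST Executive Function Composite.  Internal consistency of a member
set is summarized by standardized coefficient alpha,
α = k·r̄/(1 + (k−1)·r̄) with r̄ the mean pairwise correlation of the
sign-aligned standardized scores; since all inputs are z-standardized
first, the raw-covariance and standardized variants coincide up to
sampling detail.  A zero-variance member aborts the computation rather
than being dropped silently.

## Splits and the sampling estimator

Systematic splits assign alternating blocks of g consecutive trials
(the *grain*) to the two halves, first block to half A; g is valid when
n/g is an even integer (grains 1,2,3,4,6,8,12,24 for 48 trials;
1,2,3,4,6,12 for the 24-trial analysis).  Two structural degeneracies
make cells ineligible: grains 1 and 3 divide every credited six-run
exactly in half, forcing r = 1 for the category measure; and the
SE-adjacency constraint structurally anticorrelates odd/even SE halves.
Composites inherit ineligibility from their members.

Random splits draw half A uniformly among all C(n, n/2) subsets,
unconstrained beyond equal size.  For each of I iterations (default
100,000) the estimator computes half scores (composites are
re-standardized within each half's trial set), Pearson r across
patients, and r_SB.  Iterations with a zero-variance half or r = −1 are
excluded and counted (NaN propagation would poison the median; a
warning is logged above 1% exclusions, and all-undefined is fatal).
Negative r_SB values are retained — truncation would bias the summary.
The distribution is summarized by its median (even-length samples:
mean of the two central order statistics) and the 95% highest-density
interval, estimated as the shortest window of ⌈0.95·N⌉ sorted samples;
exact width ties break toward the lower window (ties are exact only in
rational arithmetic; in float64 they effectively never occur).

The engine is vectorized: split masks are generated in blocks of
20,000 iterations and half sums obtained as matrix products of the
patients × trials score matrix, which makes the full default grid
(15 measures × 8 grains + 100,000 random splits per measure, 128
patients) run in well under a minute on one CPU.

## Synthetic cohorts

No clinical data ship with the package; the generator produces cohorts
with the structure the analysis assumes.  Each simulated patient is a
first-order Markov responder parameterized by two stable propensities:
after negative feedback the previous dimension is repeated with
probability p_persev (otherwise a uniform switch among the other two
dimensions); after positive feedback it is repeated with probability
1 − p_setloss (otherwise a uniform switch).  Richer cognition (rule
inference, memory beyond one trial) is deliberately absent: the scored
measures depend only on these local events.

Between-patient heterogeneity — the σ²_x side of the classical
identity — comes from Beta-distributed propensities.  The packaged
default calibration is

| parameter | default | implied mean (SD) |
|---|---|---|
| p_persev  | Beta(0.75, 1.4) | .35 (.27) |
| p_setloss | Beta(0.55, 3.2) | .15 (.16) |
| n_patients | 128 | — |

chosen so that a simulated 48-trial cohort approximates the descriptive
profile of a mixed neurological inpatient sample: ≈24 correct sorts,
≈3 categories, ≈9 perseverative errors with an SD of similar magnitude,
≈3 set-loss errors, pooled conditional error probabilities ≈.4 (PE) and
≈.1 (SE).  The match is deliberately loose (±20% on means): the
hyperparameters are artifact choices, not estimates of any real
population, and at n = 128 the per-cohort mean of the rarest score
(set-loss errors) fluctuates by ~16% (1σ) across seeds, so individual
cohorts can sit anywhere in that band.  An optional truncation
distribution reproduces a clinical attrition pattern (≈12% of patients
stop before trial 48, half of those before trial 24) for exercising the
completion filters.  What passing tests on these cohorts do *not* show:
robustness to non-stationary behavior (learning, fatigue), examiner
deviations, or any diagnostic-subgroup structure — none of which the
generator emulates.

The Beta-Bernoulli oracle is the analytic anchor: with per-patient
success rates θ ~ Beta(a, b) and m = n/2 i.i.d. Bernoulli trials per
half, the correlation between half-sums is
ρ = m·Var(θ) / (m·Var(θ) + E[θ(1−θ)]) — true-score variance of a
half-sum against binomial error variance — and the full-length
reliability is 2ρ/(1+ρ).  The closed form was cross-checked against
large-sample simulation (5,000 patients: agreement within ±0.02) before
being used to test parameter recovery at the study scale (128 patients,
48 trials, 10,000 iterations: median within ±0.05 at Beta(2,2); wider
delta-method tolerances of ±0.10 and ±0.20 at mid and low reliabilities,
where patient-level Monte-Carlo noise dominates).

## Numerical and interface choices

- 1-based trial indexing throughout, matching record-table conventions.
- Degenerate inputs raise typed errors (`AdjudicationError`,
  `DegenerateVarianceError`, `UndefinedEstimateError`,
  `RecordFormatError` with row numbers) rather than returning NaN.
- CSV outputs round coefficients to 3 decimals and render structural
  gaps as `na`; the JSON result object keeps full precision and records
  seed, iteration count and package version, so reruns with an
  identical configuration are byte-identical.
- Test problem sizes: property tests run at 6–48 trials and 5–300
  patients; exhaustive-enumeration checks use ≤8 trials; the full
  default grid (100,000 iterations × 15 measures) runs once in the
  suite as the end-to-end check.

## Known limitations

- The scoring operationalizations of PE and SE are one defensible
  reading of verbal definitions; manual-based scoring may differ at
  post-completion trials.
- The continuation rule after a sixth completed category (cycling the
  rule sequence) is a package choice; high performers who would exhaust
  six categories before trial 48 are rare in the intended clientele.
- Reliability coefficients estimated here characterize a sample and an
  administration, not the instrument in general; the synthetic default
  cohort is a stand-in whose coefficients should not be quoted as
  clinical values.
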