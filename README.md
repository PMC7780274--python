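# mwcst

Trial-level scoring and split-half reliability analysis for the
Modified Wisconsin Card Sorting Test (M-WCST).

Reliability coefficients quoted in test manuals rarely transfer to the
sample in front of you: by the classical identity
rel = 1 − σ²_e/σ²_x, a coefficient depends as much on the
between-patient variance of the assessed group as on the instrument
itself.  This package lets neuropsychologists and methodologists
estimate split-half reliability of M-WCST scores *from their own
trial-level records* — a single administration per patient suffices —
instead of inducting coefficients from other samples.

From one row per administered trial (patient, trial index, chosen
sorting dimension) the pipeline:

1. **replays** the task (fixed rule order color → shape → number,
   repeated; six consecutive correct sorts complete a category and
   silently advance the rule) to recover feedback and rule state;
2. **scores** four basic measures per trial — correct sorts *n_corr*,
   categories *n_cat* (1/6 credit on each trial of a completed run, so
   any trial subset has a category score), perseverative errors *n_PE*
   (repeating a dimension after negative feedback) and set-loss errors
   *n_SE* (an erroneous switch after positive feedback) — plus the 11
   signed composites of their z-scores (errors negated), including the
   *n_cat* + *n_PE* combination that approximates the Executive
   Function Composite;
3. **splits** the 48 (or first 24) trials systematically at every valid
   grain size — alternating blocks of g consecutive trials, from the
   odd/even split (g = 1) to first/second halves (g = 24) — and into
   100,000 uniformly random equal halves;
4. **estimates** reliability per split as the Spearman–Brown-corrected
   Pearson correlation of per-patient half scores,
   r_SB = 2r/(1 + r), and summarizes the random-split distribution by
   its median and 95% highest-density interval.  Cells where the task
   structure forces a degenerate coefficient (category credit at grains
   1 and 3; set-loss errors at grain 1) are reported `na`.

A synthetic-cohort generator (Beta-distributed perseveration and
set-loss propensities driving a feedback-coupled response process)
stands in for clinical data in all tests and examples, and a
Beta-Bernoulli cohort with closed-form reliability anchors the engine
to an analytic oracle.

## Worked example

```python
from mwcst import simulate_cohort, score_cohort, sample_distribution, \
    split_half, systematic_split
from mwcst.composites import CompositeSpec

cohort = simulate_cohort(rng=7)            # 128 synthetic patients, 48 trials
scores = score_cohort(cohort, 48)          # completion filter + trial scoring
print(scores.summary().mean().round(2))

efc = CompositeSpec(("n_cat", "n_PE"))     # Executive Function Composite
dist = sample_distribution(scores, efc, n_iterations=10_000, seed=7)
print(f"r_SB median {dist.median:.3f}, "
      f"95% HDI [{dist.hdi_low:.3f}, {dist.hdi_high:.3f}]")

odd_even = split_half(scores, efc, systematic_split(48, 1))
first_second = split_half(scores, efc, systematic_split(48, 24))
print(f"odd/even r_SB {odd_even.r_sb:.3f}, "
      f"first/second r_SB {first_second.r_sb:.3f}")
```

prints

```
n_corr       24.84
n_cat         2.80
n_PE         10.70
n_SE          3.33
n_poss_PE    22.65
n_poss_SE    24.35
dtype: float64
r_SB median 0.952, 95% HDI [0.924, 0.975]
odd/even r_SB 0.992, first/second r_SB 0.821
```

This synthetic cohort averages about 25 correct sorts (half of 48
trials), three completed categories, eleven perseverative and three
set-loss errors.  The Executive Function Composite's sampled
split-half reliability has median .95 — the random-split estimate a
practitioner would report — with a 95% HDI quantifying split-to-split
uncertainty.  The fine-grained odd/even split gives a higher, the
first/second-half split a lower coefficient, bracketing the
sampling-based estimate; the gap reflects non-stationarity of
performance across the session, which coarse grains absorb into the
between-half difference.

The same analyses run from the shell:

```sh
mwcst simulate --n 128 --seed 7 --out records.csv
mwcst run-all --input records.csv --variant complete-48 \
      --iterations 100000 --seed 7 --outdir results/
```

`run-all` writes the per-trial score table, per-patient summary,
descriptives, the alpha table for the 11 composites, the full
reliability grid (15 measures × grain sizes, plus random-split median
and HDI, `na` for ineligible cells) and a `results.json` with seed and
iteration provenance; reruns with the same configuration are
byte-identical.

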