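# dietqual

Estimating population diet quality from repeated 24-hour dietary recalls.

A single 24-h recall is a noisy snapshot of what a person *usually* eats:
day-to-day variability is large, episodically consumed foods (fish, greens,
whole fruit) are zero-inflated, and dietary components are correlated with
each other and with energy. Naively scoring one or two recalls per person
badly over-disperses the population distribution of diet quality and biases
the share of the population meeting recommendations. `dietqual` implements
the full workflow used in large diet surveillance cohorts such as the
Hispanic Community Health Study / Study of Latinos:

1. **HEI-2010 scoring** — the Healthy Eating Index 2010: 12 density-based
   components (9 adequacy, 3 moderation) summing to 0–100. Each component
   scores linearly between a zero-score and a maximum-score density anchor,
   e.g. total fruit ≥ 0.8 cup-equiv/1000 kcal for full points, sodium
   ≤ 1.1 g/1000 kcal, fatty-acid ratio (PUFA+MUFA)/SFA ≥ 2.5, empty calories
   ≤ 19% of energy.
2. **Cohort-assembly exclusions** — ordered filters (age, heritage, recall
   availability/reliability, sex-specific energy percentiles) with a
   first-failure audit table.
3. **A multivariate measurement-error model** for usual intake: on a
   transformed scale (Box–Cox λ = 0.25 for amounts and energy, log for the
   fatty-acid ratio; centered, variance 2), recalls decompose as

   ```
   z_ijk = x_ij' β_k + b_ik + e_ijk,     b_i ~ N(0, Σ_b),  e_ij ~ N(0, Σ_e)
   P(consume_ijk) = Φ(x_ij' γ_k + u_ik)  (episodic components)
   ```

   with covariate adjustment for sex, age, heritage, field center, weekend
   (incl. Friday), reported more/same/less-than-usual amount, and recall
   sequence. Usual intake is the within-person expectation on the natural
   scale times the consumption probability.
4. **A Monte Carlo pseudo-population** — M (default 100) usual-intake draws
   per participant from the posterior of the person effects given their
   recalls — from which survey-weighted, age/sex-standardized mean scores
   and percent-at-maximum (share meeting each recommendation) are computed,
   with Rao–Wu rescaling bootstrap SEs honoring the stratified-PSU design.
5. **Correlates regression** — survey-weighted least squares of the
   recall-average HEI total on participant characteristics, with backward
   selection at the p = 0.1 stay level (categorical blocks tested jointly;
   field center and heritage forced to stay).

Because the real cohort data are restricted-access, the package ships a
synthetic-cohort generator (`dietqual.synthetic`) that reproduces the data
*structure* — stratified two-stage weighted design, two noisy recalls,
zero-inflated episodic components, between-component correlation — with
known ground truth, so every stage can be validated by parameter-recovery
experiments.

## Worked example

`examples/simulate_and_recover.py` generates an 800-person cohort with two
recalls each, fits the measurement-error model, and compares pseudo-population
summaries with the generator's truth:

```
cohort: 800 participants, 1600 recalls
episodic components: ['whole_fruit', 'greens_beans', 'seafood_plant_protein']
                       true_mean  est_mean  true_pct_at_max  est_pct_at_max
total_fruit                 4.16      4.05             31.8            28.1
whole_fruit                 4.02      4.02             45.1            43.8
...
sodium                      5.47      5.83              6.9            10.5
empty_calories             17.76     17.69              7.6             9.3
total                      75.21     75.75
```

`true_pct_at_max` is the survey-weighted share of the population whose *true*
usual intake earns the component's full points; `est_pct_at_max` is the same
quantity recovered from the noisy recalls through the measurement-error
correction. Raw single-day scores would miss these badly — the
over-dispersion and bias are demonstrated in
`tests/test_acceptance.py::test_correction_tightens_distribution_and_reduces_bias`.

Other examples: `score_profile.py` (one profile, 12 component scores),
`survey_bootstrap.py` (Rao–Wu vs Taylor vs naive SEs),
`correlates_regression.py` (backward-selected survey regression),
`full_pipeline.py` (everything from a single `RunConfig`). A thin CLI mirrors
the pipeline: `dietqual simulate|score|fit-usual|summarize|regress|run`.

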