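# Methods

## Outcome construction

A food-log *entry* is one logged consumption event with free-text brand and
description, a serving unit and a serving count. Because serving amounts
are unstandardised across foods, the analysis counts entries rather than
amounts. Three independent binary classifiers label each entry:

* **fast food** — the normalized brand contains a known chain name as a
  substring;
* **soda** — the normalized brand contains a soda drink name as a substring
  *and* the normalized description contains none of the tokens `diet`,
  `lite`, `light`, `zero` (matched as whole tokens, so `lite` cannot fire
  inside `politely`);
* **fresh fruit & vegetables (F&V)** — the normalized brand or description
  contains a produce term as a whole token sequence and no excluder token.
  Juices are excluded by design (their healthfulness as a produce serving
  is contested), as are processed preparations (jam, pie, dried, …).

Normalization lowercases, deletes punctuation (so `Coca-Cola` and
`CocaCola` deliberately collide; the shipped keyword lists therefore
include collapsed variants such as `cocacola`) and collapses whitespace.
Inclusion lists match as substrings of the brand — robust to strings like
"mcdonalds fries" — while excluders and F&V terms match as whole tokens to
avoid false vetoes. An entry may carry several labels (the classifiers are
independent); an entry carrying none is excluded from consumption outcomes
but still marks its day as active. The keyword inventories are
configuration files, not code; the shipped F&V list is a synthetic
approximation assembled from standard produce-group items, since no
canonical list exists.

Classifier quality is audited by precision only — a seeded random sample
(default 50) of predicted positives per category is manually labeled and
the true-positive fraction reported. Recall cannot be measured without
exhaustive ground truth.

Aggregation runs in three stages: within participant-day (daily counts),
across each participant's *active days* (days with at least one entry of
any kind; empty calendar days are excluded from the denominator), then
across participants within a zip (unweighted mean of participant rates).
The BMI outcome is the fraction of BMI-reporting participants with BMI
strictly greater than 25. Participants need ≥ 10 active days; zips need
≥ 30 participants. Zip codes are always 5-character strings with leading
zeros preserved; fractions live on [0, 1] in all files and only become
percents at presentation.

## Food-environment covariates

Tract-level measures (fraction of residents beyond 0.5 miles from a
grocery store; binary food-desert status) are aggregated to zips through a
tract→zip crosswalk as a population-weighted average:
`zip value = Σ(tract value · tract population) / Σ(tract population)`.
The 0.5-mile threshold is used for rural and urban zips alike. Grocery
access is stored with the "fraction *within* 0.5 miles" sign convention so
that high access is the above-median side. A zip is a food desert when its
weighted tract measure reaches 50%.

Fast-food access is the chain fraction among the restaurants nearest the
zip centroid — at most 1,000 within 40 km, emulating a capped
point-of-interest query. Distances are great-circle (haversine, Earth
radius 6371 km); ties keep stable input order. The denominator is
*restaurants*, not all businesses. A zip whose radius contains no
restaurant gets a missing value rather than zero.

## Treatment assignment and matching

For each factor (median family income, college fraction, grocery access,
fast-food access) zips are dichotomised at the sample median, boundary
values on the treated side; the treated direction is high income, high
education, high grocery access and *low* fast-food access, so "treated"
is always the putatively favourable environment. A quartile variant
(top vs bottom quartile, middle discarded) is available for dose-response
sensitivity analysis. Subgroup analyses restrict first to zips where one
ethnic group holds ≥ 50% of the population, so cut points are
subgroup-specific.

Each treated zip is matched one-to-one with replacement to the control zip
nearest under `d_w(i,j) = sqrt(Σ_k w_k (z_ik − z_jk)²)` on covariates
standardized by the full pre-matching sample SD. The weights `w ∈ (0, 10]^k`
are tuned by a small genetic algorithm — population 50, 30 generations,
tournament selection (size 3), uniform crossover, log-scale mutation,
two-member elitism, a few random immigrants per generation, early stopping
after 8 generations without improvement — whose fitness is the mean
absolute SMD of the induced match. Because the induced match depends only
on the weight *direction*, initial weights and immigrants are sampled
log-normally around identity, and on small instances (≤ 1,000
treated×control cells) the initial population is additionally seeded with
the best direction from a coarse deterministic lattice over [0.1, 1]^k; a
final coordinate-wise multiplicative hill-climb polishes the best vector.
The identity weight vector is always in the initial population, so the
result is never worse than plain equal-weight nearest-neighbour matching.
Everything is reproducible from a single seed.

Balance uses the conservative SMD convention: mean difference divided by
the *post-matching control-group* sample SD, which is typically smaller
than the pooled pre-matching SD. A match is balanced when every covariate
|SMD| < 0.25. If the unrestricted match is unbalanced, a per-covariate
caliper in standardized units starts at 2.5 and shrinks by 0.1 until
balance is reached; treated units with no admissible control are dropped
and reported, narrowing the estimand from the ATT to a caliper-restricted
ATT. If the caliper reaches zero without balance, the experiment raises
rather than reporting an unbalanced estimate. The caliper is applied per
covariate because no propensity score exists in this fully nonparametric
design.

## Estimation and inference

The ATT for each outcome is the relative difference in percent of the
treated pair-mean over the control pair-mean (a control matched to several
treated zips counts once per pair). The ratio of pair-means is used rather
than the mean of pair-ratios for robustness to near-zero control values; a
zero control mean is an error, not a zero.

Confidence intervals and p-values come from a nonparametric bootstrap with
1,000 replications that resamples whole matched pairs — never individual
zips — with the 2.5/97.5 percentile interval and a two-sided sign-crossing
p-value floored at 1/replications. One refinement matters: with-replacement
matching reuses controls (the reuse factor `Σ m_j²/n` is ≈ 2 at 250 pairs
in four dimensions), making pairs that share a control statistically
dependent. Resampling pairs as independent units then understates the
sampling variance by ≈ 20% in SE terms. The bootstrap therefore resamples
*clusters* of pairs sharing a control — the independent units — which
restores the SE to within a few percent of the truth (verified by
simulation against the across-seed SD of the estimator). With all-distinct
controls this reduces exactly to the plain pair bootstrap. A two-sided
paired t-test on pair differences is computed alongside as a parametric
cross-check; zero-variance differences yield a flagged NaN.

Null-treatment (discriminant-validity) experiments run the same machinery
with a covariate chosen to be unrelated to diet; the Pearson correlation
of the null covariate with each study factor is reported, and factors
nearly collinear with the null covariate (|r| ≥ 0.95) are excluded from
the matching set since a median split of a covariate cannot be balanced on
itself. A generic Pearson-correlation-with-reference helper (two-sided
t-test p-value, pairwise-complete) supports validation against external
regional measures.

## Synthetic data generator

The generator emulates the study's inputs, with defaults set to the
study-scale conditions: 9.30 logged entries per participant-day, mean 197
active days with a floor of 10, ~119 participants per zip, and a zip
composition of 78% white-majority, 6% Hispanic-majority and 4%
Black-majority zips.

Covariates come from a Gaussian copula with a configurable 4×4 correlation
matrix (defaults: income–education 0.6, grocery–fast-food 0.3, weaker
cross terms; validated positive semidefinite) mapped to log-normal income
(median $65k) and logistic-transformed fractions. Outcomes follow

```
outcome_z = baseline · (1 + Σ_f δ_f T_f(z) + Σ_{g,f} δ_{g,f} T_f(z) 1[majority g]) · exp(ε)
```

with ε ~ N(0, noise_sd), noise_sd defaulting to 0.05, baselines 0.90 /
0.35 / 0.25 daily entries for F&V / fast food / soda and 0.55 for the
overweight fraction. Treatment indicators T_f are median splits of the
generated covariates; a dose-response mode replaces the indicator with a
signed rank exposure in [−1, 1] so quartile contrasts exceed median
contrasts. Effects are multiplicative because results are reported as
relative differences. The default effect map uses effect sizes of the
magnitude the design targets (roughly ±3–14% depending on factor and
outcome); recovery tests inject a single effect with the rest zeroed so
ground truth is exact.

Food logs are rendered per participant: active days from a shifted
negative binomial, a participant-specific gamma-heterogeneous rate per
category (shape 10, a free parameter since real per-participant
overdispersion is unknown), Poisson daily counts, and brand/description
strings sampled from the category vocabularies plus distractors that
deliberately stress the excluder logic ("Diet Coke", "Pepsi Zero Sugar",
"Apple Juice", "Light string cheese"). BMI is normal (SD 4) around a zip
mean calibrated so the overweight fraction is recoverable; 0.08% of
participants omit BMI. Geometry: 1–8 tracts per zip with jittered
"beyond 0.5 miles" fractions re-centred so the crosswalk reproduces the
configured access, and business points scattered within a few km of
centroids that are spaced widely enough for 40 km queries to stay
zip-local.

What the generator does *not* emulate: app-user self-selection, seasonal
or longitudinal structure, spatial autocorrelation between neighbouring
zips, measurement error in the covariate sources, or real keyword
ambiguity beyond the built-in distractors. Passing recovery tests
therefore demonstrates the statistical machinery is correct and unbiased
under the generator's assumptions, not that real data meet those
assumptions.

## Problem sizes and numerical choices

Simulation-based tests use 500 zips (the scale at which median splits give
250 matched pairs), 20–100 seeded runs per property, and food-log
round-trips with ~200 participants per zip over ~25 active days; these
sizes give Monte-Carlo error comfortably below the asserted tolerances
(e.g. recovery of injected effects to < 1 percentage point median absolute
error). The bootstrap keeps the conventional 1,000 replications. Seeds
propagate through `numpy` `SeedSequence` spawning so every stage is
independently reproducible; derived seeds stay below 2³¹. Degenerate
inputs (all-identical split values, zero-variance covariates, empty
control pools, zero-population zips, zips with no BMI reporters or no
nearby restaurants) raise or flag missing values explicitly rather than
silently producing numbers.

## Known limitations

* The design is cross-sectional and matching-based; estimates are
  associations under covariate balance, not causal effects. Unobserved
  confounding is out of scope.
* No multiple-testing correction is applied across the factor × outcome ×
  subgroup grid.
* The shipped keyword lists are small curated inventories; real-world
  food-log vocabularies are far larger, and precision/recall on real text
  will differ from the synthetic round-trip figures.
* Multilevel (participant-level) bootstrapping is not implemented; all
  inference is at the zip level.
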