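# Methods

## Scoring model

The molecular score is linear in transformed inputs:
`score = Σ_j β_j (x_j − x̄_j) / ln 2` with published Cox log-hazard
coefficients `β_j` and centering means `x̄_j` shipped as data
(`mdsrisk/data/ipssm_coefficients.json`). Dividing by ln 2 puts the score on
a hazard-doubling scale and makes the cohort-average patient score 0.
Transforms: blasts capped at 20 % and divided by 5; platelets capped at 250
×10⁹/l and divided by 100; hemoglobin untransformed; cytogenetics as the 0–4
IPSS-R category index; gene variables binary; the residual-gene count capped
at 2. Categories are cut at −1.5, −0.5, 0, 0.5, 1.5 with the upper bound
inclusive, so a score of exactly 0 is "ML" and a score exactly on a cutpoint
falls in the more favorable category. Scores are reported to 4 decimals but
categories are always computed from the unrounded value.

The coefficient file was transcribed from the score's public reference
implementation; the structural contract (31 distinct gene variables = 16
main-effect + 15 residual genes, five ascending cutpoints, best/worst
fill-ins oriented by weight sign) is validated on every load. A conformance
note: the transcription has not been re-verified against the public
calculator from inside this repository; the structural validators and the
weighted-sum oracle in the tests pin the arithmetic, not the provenance of
each constant.

The clinical score (IPSS-R) is the standard point system (cytogenetic
category 0–4 points; blasts ≤2→0, >2–<5→1, 5–10→2, >10→3; hemoglobin ≥10→0,
8–<10→1, <8→1.5; platelets ≥100→0, 50–<100→0.5, <50→1; ANC ≥0.8→0, <0.8→0.5)
with category cuts at 1.5/3/4.5/6, upper-inclusive. A patient lacking any
required input — in practice usually the neutrophil count — yields a
first-class "not computable" result rather than an error, so validation
analyses can restrict to the evaluable subset the way registry analyses do.

## Missing-data scenarios

Unknown variables are resolved per scenario: *mean* imputes the centering
mean (contribution exactly 0), *best*/*worst* impute the configured extreme
fill-ins. For the residual-gene count the best case is the observed count,
the worst case observed + unassessed (capped at 2), and the mean case the
observed count plus the summed prevalences of the unassessed genes (capped at
2), with per-gene prevalences shipped alongside the coefficients. Whether the
original model's mean scenario is exactly "contribution zero" is not
derivable from the validation literature alone; the choice is isolated in one
branch of `compute_score` and documented here so users can compare
conventions. With no unknowns all three scenarios coincide — an invariant the
tests enforce.

Unknowns are never silently defaulted upstream either: a TP53 single-mutation
patient whose del(17p) or CN-LOH status is unknown gets classification
"unknown" (and a score interval) only when the flag would actually decide the
call; an SF3B1-mutated patient with an unassessed co-mutation gene gets a set
of possible subtypes that scenario scoring consumes.

## Survival statistics

Kaplan–Meier uses the product-limit form with events processed before
censorings at tied times and Greenwood standard errors. Leukemic
transformation is estimated by default as an Aalen–Johansen cause-specific
cumulative incidence with death-without-transformation as the competing risk;
with zero competing events this reduces exactly to 1 − KM, which is also
exposed (censor-at-death) since validation reports rarely state their
estimator. Harrell's c treats pairs (i, j) as comparable iff `t_i < t_j` and
patient i had the event; concordant iff the earlier-event patient has the
higher score; score ties count 0.5. For the transformation endpoint the
c-index censors competing deaths (cause-specific concordance) — a documented
limitation, not a competing-risk concordance. For category-valued predictors
the ordinal index is used, which produces many ties; the continuous score
(molecular) and points (clinical) are the defaults. No confidence intervals
are attached to c.

These estimators are deliberately implemented from first principles — they
are the quantities this pipeline exists to compute — and the test suite
cross-checks them against lifelines (KM, Aalen–Johansen), scikit-survival
(concordance) and O(n²) brute-force enumeration.

## Restaging

The molecular ML and MH categories are merged into one "Moderate" level so
both systems are five-level ordinals; the shift is the molecular minus the
clinical ordinal, positive = up-staged. Only the molecular side is merged.
Patients whose molecular category is scenario-dependent enter the
distribution and restaging via the mean scenario, with the affected count
disclosed in the report.

## Synthetic cohort generator

The generator emulates the *structure* of a 626-patient single-center
validation series, not its raw data:

* **Lesions.** TP53 carriers are planted with the published mechanism
  composition (32 single / 7 two-mutation / 16 mutation+del(17p) / 12
  mutation+CN-LOH = 67 carriers, 35 multihit); SF3B1 carriers (199) split
  into isolated-del(5q) (9 %), no-co-mutation (82 %) and other (9 %)
  subtypes; FLT3 (7), KMT2A-PTD (6) and NPM1 (4) are planted as counts; the
  remaining score genes are independent Bernoulli draws at literature-scale
  prevalences. In `exact_marginals` mode these counts are hit exactly
  (assignment shuffled by seed); in `probabilistic` mode each count/626
  becomes a per-patient probability. `reference_n` decouples the counts from
  the simulated cohort size.
* **VAFs** are Beta-distributed (mean ≈ 36 %); CN-LOH carriers draw from a
  truncated-normal high-VAF component (mean 66, sd 9, truncated 40–95) so
  most but not all exceed the 55 % surrogate threshold — which is what makes
  surrogate-discordance analyses non-trivial.
* **Cytogenetics and clinical values.** The karyotype category is drawn from
  a five-point distribution; hemoglobin (truncated normal), platelets
  (log-normal) and the two-part blast distribution (mass below 2 % plus an
  exponential tail capped at 19 %) are conditioned on that category, coupling
  marrow failure to karyotype severity. Biallelic TP53 forces the category to
  at least "poor". The neutrophil count is missing in 27.8 % of patients,
  reproducing the evaluable fraction (452/626) of the reference series.
  These families are convenience choices — nothing claims they match the real
  cohort's marginals; only the resulting category mix is calibrated, once,
  to the published 15/41/11/7/12/14 % within ±3 points per category, and the
  tuned parameters are committed as data (`data/generator_default.json`).
* **Survival.** Endpoint times are exponential with hazard
  `h0 · 2^score` (mean-scenario molecular score), h0 = 0.012/month for death
  and 0.0035/month for transformation; transformation competes with death;
  leukemia-free survival fails at the first of the two. Administrative
  censoring is uniform on 6–228 months, matching a long-follow-up registry.
  One score unit doubles the hazard by construction, so discrimination is
  testable: the molecular c-index must beat the clinical one, and switching
  the hazard link off must pin c at 0.5. A Weibull shape parameter is exposed
  but defaults to 1 (exponential).
* **Seeding.** One integer seed spawns three independent sub-streams
  (lesions / clinical / survival) via `numpy.random.SeedSequence`, so adding
  a downstream stage never perturbs upstream draws and cohorts are
  byte-reproducible.

What passing tests on this cohort do *not* show: real MDS has correlated
co-mutation patterns beyond the SF3B1 exclusion rule, non-exponential
hazards, informative censoring, and clinical-value distributions the
generator does not attempt to match. The calibration round-trips demonstrate
internal consistency of the pipeline, not external validity of the score.

## Problem sizes and numerical choices

The analysis scripts and acceptance computation use 25 cohorts of n = 626 for
the stochastic calibration quantities, one exact-marginals cohort for the
planted-count checks, and pools of five cohorts where per-category medians
are needed (single-cohort KM medians for the two moderate categories, ~7–11 %
of 626 patients each, are too noisy to order reliably; KM medians that never
reach 0.5 under censoring are treated as +∞). Concordance is computed by
vectorized pair enumeration (exact, no approximation). Scores compare equal
to the independent weighted-sum oracle to 1e−9; category boundaries are
exact comparisons on unrounded floats. Tri-state flags parse
yes/no/empty; parsing is locale-independent (decimal points only).

## Known limitations

* Karyotype strings are not parsed; cytogenetics enter as a precomputed
  category plus lesion flags, and CN-LOH is an input flag, not derived.
* The flag-based fallback for the IPSS-R cytogenetic category covers only the
  encoded abnormalities (normal/del(5q) → good, −7/del(7q) → poor, complex →
  very poor, isolated del(17p) → intermediate); anything else requires the
  precomputed category.
* No pathogenicity filtering: mutation calls are assumed oncogenic.
* No age adjustment of either score, and no per-patient survival-probability
  prediction — scores and categories only.
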