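# Methods

## The problem

Artificial-grammar-learning (AGL) experiments expose human or animal
subjects to sequences generated by a structured grammar and then test
whether they discriminate conforming from non-conforming sequences. The
literature is heterogeneous in every dimension that matters for synthesis:
species (human adults and children, songbirds, non-human mammals), outcome
measures (accuracy against chance, endorsement, go/no-go, serial reaction
times, looking times, head turns, sequence reproduction), reporting
conventions (means with SDs, confidence intervals, multiple test
sessions), and grammar design (modality, vocabulary size, adjacent vs
non-adjacent dependencies, repetition of training items at test). This
package implements the full meta-analytic pipeline for such a literature:
outcome harmonization into one effect-size family, a multilevel
random-effects meta-regression, moderator and subgroup analyses, and
publication-bias diagnostics, together with a synthetic-data generator so
the whole chain is testable without any external data.

## Effect-size harmonization

All outcomes are converted to the standardized-mean-difference family.
For chance-comparison paradigms (accuracy, yes/no, go/no-go, scale
judgement, forced choice, head turn, frequency estimation):

    d = (mean − chance) / SD_within.

For paired paradigms (serial reaction time, sequence production, looking
time), d is the grammatical-vs-ungrammatical difference divided by the
average SD over all sessions of both conditions. Using the raw SD (rather
than the SD of the paired differences) treats the two conditions as
perfectly correlated, which makes the standardizer an upper bound and the
effect size conservative.

Cohen's d is corrected to Hedges' g with J = 1 − 3/(4·df − 1), df = n − 1,
and the sampling variance is the Borenstein-convention

    v_g = (1/n + d²/(2n)) · J².

df = n − 1 is used for both J and v_g because every supported design is a
one-sample or within-subject comparison; n is the participant count (the
largest session n when sessions re-test the same sample, never the sum).

Sign conventions are centralized in one table: positive g always means a
structure-conforming advantage. For RT that means faster responses on the
trained structure; for looking time, longer looking at violations (the
novelty effect), so both paired paradigms negate the raw
grammatical-minus-ungrammatical difference. Where a study's authors
interpreted a grammatical-stimulus preference as learning (a familiarity
effect), the coded `familiarity_resign` flag negates g after the fact;
the variance is unchanged, and the operation is an involution.

Session pooling weights means by per-session n and pools SDs through
variances with n − 1 weights (generalized to any session count).
Confidence intervals reported in place of SDs are inverted under the
t-distribution model, SD = √n·(upper − lower)/(2·t_crit(n−1)), the more
conservative choice relative to a normal-based interval. Proportions on a
0–100 scale are detected by the chance value and rescaled at ingest; g is
scale-invariant so this only aids validation.

Degenerate inputs: n = 1 gives J = 0 and therefore g = v_g = 0 without
error from the variance formula, but harmonization of a full record
requires n ≥ 2 so the effect carries information; sd ≤ 0 and empty
session lists are rejected with named-field errors.

## The multilevel model

Articles contribute several effects (multiple experiments, multiple
tests), so effects cannot be treated as independent. The model is the
standard three-level meta-regression

    g_ij = x_ij'β + u_i + w_ij + ε_ij,
    u_i ~ N(0, σ²_article),  w_ij ~ N(0, σ²_study),  ε_ij ~ N(0, v_ij),

with v_ij known from harmonization. Variance components are estimated by
REML with β profiled out by GLS. The marginal covariance is block
diagonal over articles, so all linear algebra runs per article block,
batched over blocks of equal size; the analytic REML gradient (trace and
quadratic-form identities in the projected precision) feeds a bounded
L-BFGS-B optimizer on (σ²_article, σ²_study) ∈ [0, ∞)² started from
(0, 0), (0.1, 0.1) and (1, 1). Fixed deterministic starts make fits
reproducible; convergence is to ~1e−12 relative negative log-likelihood,
and the number of starts agreeing with the best optimum is recorded on
the fit. Components are bounded at zero, never negative. When an article
contributes a single effect, σ²_article and σ²_study are not separately
identifiable from that article; both components are retained and the
optimizer is free to push either to zero (the cross-check against
metafor's rma.mv confirms identical behavior).

Inference is the t-method (Knapp–Hartung-type): each coefficient's
t = β̂/SE is referred to t(k − p) where k is the number of effects and p
the number of coefficients; CIs use the same df. Omnibus moderator tests
divide the joint Wald statistic of the moderator's m coefficients by m
and refer it to F(m, k − p). Cochran's Q is computed from the weighted
fixed-effect fit of the same design (weights 1/v) with df = k − p, i.e.
k − 1 for the intercept-only model, regardless of the random-effects
structure — the standard definition.

Categorical moderators expand by treatment coding (reference = first
level alphabetically) for moderated fits, and by cell-means coding for
subgroup estimation, so each subgroup coefficient is that level's
weighted mean effect with shared variance components. Rows with missing
values in a used moderator are excluded from that analysis only, with a
logged count. Subsets with constant moderators (e.g. a class tested only
in one modality) carry a skip set so downstream tables omit untestable
moderators instead of erroring.

## Publication-bias diagnostics

Peters' test enters inverse total sample size (1/n) as the sole moderator
in the same multilevel machinery and reports the t-method t of its slope
with df = k − 2. Peters' original formulation targets log odds ratios
with binomial weights; for standardized mean differences the moderator
route is the natural adaptation and keeps all inference consistent with
the rest of the model. Funnel coordinates pair each effect with its
standard error √v_g, grouped by animal class, with the intercept-only
multilevel estimate as the reference line.

## The synthetic-data generator

The generator draws from exactly the three-level model above, with the
moderator structure of the real literature: an animal class per article
(≈64% human adult, 24% bird, 7% child, 5% non-human mammal), per-class
species lists, human n in 10–40 and non-human n in 4–12, a paradigm mix
dominated by reflection-based tasks, log training length uniform on
ln 50–ln 5000 tokens, and binary structural features. Non-human mammals
are generated auditory-only, adjacent-dependency, no-repetition — the
confounding that forces those moderators to be skipped in that subgroup.
Defaults are ~66 articles with 1–4 effects each (~156 effects), true
overall effect 1.0, σ²_article = 0.3, σ²_study = 0.1.

Sampling variances are v = 1/n + (x'β)²/(2n): the 1/n + d²/(2n) form of
the SMD family evaluated at the design-predicted effect, not the realized
random effect. This is deliberate. If v depends on the realized u_i + w_ij,
inverse-variance weights are correlated with the outcome and *every*
weighted estimator is biased downward (we measured ≈ −0.03 on a mean of
1.0, with 95% CI coverage dropping to ≈ 0.91); that is a property of such
a generator, not of the estimator under study, and it would make
estimator calibration untestable. With exogenous variances the REML
estimates are unbiased to Monte-Carlo precision and coverage is nominal.

`simulate_raw_studies` emits per-paradigm raw summary statistics by
inverting the harmonization formulas (choose an SD on the outcome's
natural scale, back out the mean from the target d), covering
multi-session reporting, CI-only reporting, and familiarity re-signing;
harmonizing them reproduces the generated effect to machine precision.
The generator therefore exercises the pipeline's algebra, not trial-level
behavior — it does not simulate learning, grammars, or stimuli, and its
round-trip exactness says nothing about extraction error in real coding.

Selection bias is modelled as stochastic thinning with a (g, se) →
retention-probability rule; the default rule retains small imprecise
effects below a g threshold with low probability, which produces the
positive small-study asymmetry Peters' test detects.

## Calibration experiments and problem sizes

Two simulation experiments validate the inference machinery end to end,
run both in the test suite and by `scripts/acceptance.py`:

* **Parameter recovery and coverage** — 500 replicates of 40 articles × 3
  effects at μ = 1.0, σ²_article = 0.3, σ²_study = 0.1. Bias of each
  estimate is tested against zero at the 95% Monte-Carlo band
  (|bias| ≤ 1.96·MCSE, the standard simulation-study criterion); 95% CI
  coverage of μ must lie in 0.95 ± 0.03.
* **Peters type-I error** — 1000 replicates of an unbiased null generator
  (30 articles × 2 effects); the rejection rate at α = 0.05 must lie in
  0.05 ± 0.02.

A dense grid search over (σ²_article, σ²_study) ∈ [0, 2]² on instances
with k ≤ 8 provides an optimizer-independent check that the REML optimum
is a global one to 1e−4 in restricted log-likelihood. Independently, the
fit is cross-checked against frozen full-precision output of R metafor's
`rma.mv` (same model, same data, `test="t"`) covering the intercept fit,
variance components, restricted log-likelihood, Q, omnibus F, cell-means
subgroup estimates, and Peters' regression.

## Known limitations

* The reproduction of the published coded-literature numbers requires the
  original per-study coding sheet (`data/data_s2.csv`); the repository
  ships without it, so those two acceptance tests fail until the sheet is
  supplied. All machinery needed to reproduce them is in place and is
  exercised on synthetic sheets of identical schema.
* The paired-design variance uses total n in the one-sample formula (the
  conservative correlation-1 treatment); if the true within-subject
  correlation is lower, precision is understated.
* No robust (cluster-sandwich) variance estimation, no Bayesian
  estimation, no trim-and-fill or selection-model bias correction.
* Whether CIs reported by original authors used t or normal critical
  values is unknowable from the coded sheet; the t assumption is the
  conservative default.
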