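# Methods

This note documents the models, estimators and design choices behind the
package, and what the synthetic cohort does and does not establish.

## Measurement model and scoring

The AQoL-6D (adolescent version) has 20 ordinal items in six dimensions —
independent living (4 items), social and family relationships (3), mental
health (4), coping (3), pain (3), senses (3) — with higher codes meaning
poorer QoL.  Items default to five categories; the container types accept
any per-item category count, and the 4/3/4/3/3/3 structure is asserted
only where the canonical instrument is required.

Per dimension we compute the unweighted total and the standardised score
`100 (max_total − total)/(max_total − min_total)`, anchored at the scale's
theoretical best/worst states (not the observed minima/maxima: the
standardised score is defined against the instrument's anchors, and using
observed extrema would make scores cohort-dependent).  Dimension scores
require complete dimensions; there is no pro-rating, matching the
complete-case analysis convention used throughout.

**Utility.**  The published adolescent utility algorithm is proprietary,
so utility is computed through a pluggable `UtilitySpec`.  The packaged
surrogate uses the multiplicative-disvalue form standard for
multi-attribute utility instruments: with per-dimension disvalue
`dis_d = 1 − S_d/100` and weights `w_d ∈ (0, 1]`,

    disutility = (1 − Π_d (1 − w_d · dis_d)) / (1 − Π_d (1 − w_d)),
    utility    = 1 − disutility,

which maps the best state to exactly 1 and the worst to exactly 0 and is
monotone non-increasing in every item code.  An additive rule is also
available.  Packaged weights (independent living 0.45, relationships 0.35,
mental health 0.50, coping 0.35, pain 0.40, senses 0.25) express the usual
ordering — mental health and functioning weigh more than senses — and were
fixed together with the generator calibration (below).  Users holding the
licensed weights can supply them as a `UtilitySpec` without touching the
rest of the pipeline.

Cronbach's α uses the textbook variance decomposition on cases complete
within the dimension (listwise within dimension), favouring
reproducibility over sample retention.

## Polychoric structure and layout

Polychoric correlations are estimated in two steps: thresholds from the
univariate margins (standard-normal quantiles of cumulative proportions),
then a bounded 1-D likelihood maximisation over the latent correlation
ρ ∈ [−0.999, 0.999] with thresholds fixed.  Rectangle probabilities of the
discretised bivariate normal are computed from Owen's T function, which is
accurate to ~1e-14 — far below the 1e-7 tolerance this module documents —
and is verified in tests against an independent grid-search oracle built
on scipy's multivariate-normal CDF (agreement within 0.002, and within
0.02 of the generating ρ at n = 50,000).  Zero-margin categories collapse
adjacent thresholds; a single observed category is an error.

The network layout applies classical (Torgerson) MDS in two dimensions to
`d_ij = sqrt(2 (1 − r_ij))`.  The MDS variant and the dissimilarity transform are documented
choices rather than reconstructions of any particular published figure;
both the transform and the edge-display threshold (default r ≥ 0.3) are
configurable.  Negative
eigenvalues of the double-centred matrix are truncated with a warning, and
each axis is sign-fixed (largest-magnitude coordinate positive) so the
embedding is deterministic up to rigid motion.

## Latent class model

Multinomial LCA: items independent given class.  The EM fit uses random
Dirichlet(1) responsibility starts, `n_restarts = 20`, relative
log-likelihood tolerance 1e-6 and at most 1000 iterations; the best
converged restart by final log-likelihood wins, and everything is
deterministic given the seed.  These are engineering defaults chosen for robustness — restarts guard
against local maxima in a likelihood that is multimodal by construction.

A smoothing floor of 1e-6 is applied to the category probabilities after
each M step (with renormalisation) so that sampling zeros — inevitable
when a class never exhibits a rare category — cannot drive held-out
likelihoods to −∞.  This is a deliberate, small deviation from raw
maximum likelihood.  Consequence: the EM ascent property holds exactly
only between floor-free updates; across floored updates the trace can dip
by amounts at the floor scale, so trace monotonicity is asserted with
slack 1e-7·(1+|loglik|), which also absorbs float64 logsumexp round-off at
cohort-scale likelihoods (|loglik| ≈ 2·10⁴).

Fitting requires complete cases (missing-at-fit is an error, not
marginalised), matching the 1067-of-1107 analysis convention.  Modal
assignment breaks ties toward the lowest class index.  Number of free
parameters: `p = (K−1) + K·Σ_j (C_j − 1)`; AIC = −2ℓ + 2p;
BIC = −2ℓ + p ln N.

**Canonical class order.**  Mixture likelihoods are label-invariant, so
reported classes are permuted into a severity order: class 1 has the
highest modal-member mean utility, class K the lowest.  For K = 4 the
middle pair is ordered by mean standardised pain score — the class with
worse pain (lower pain score) is reported third, as "moderate-phy" — so
the two moderate classes are named by *what* is impaired, not by a
utility difference that may be small.

## Choosing the number of classes

Folds: seeded near-equal 10-fold partition; leave-one-site-out (one fold
per recruitment centre); split-half (seeded 50/50, both directions — i.e.
2-fold).  Every fold spec is checked to be a disjoint, exhaustive
partition.

For each (K, fold) the model is fitted on the training portion and the CV
table records the training-model indices (log-likelihood, AIC, BIC) and
held-out analogues (held-out log-likelihood; held-out BIC/AIC penalised
with `ln N_test`).  The **default selection index is the mean
training-model BIC across CV sets**: cross-validation here serves to
stabilise the fitting index against sampling noise, which is how the
class-enumeration literature applies it.  Selecting instead on held-out
BIC double-penalises — the held-out likelihood already punishes
overfitting, and adding `p ln N_test` on top systematically favours
too-few classes — which is observable on the calibrated profile (held-out
BIC picks K = 2–3 while training BIC and held-out log-likelihood both pick
the generating K = 4).  Any recorded index can be selected on via
`select_k(cv, index=...)`.

Diagnostics: an elbow indicator (first K whose next improvement falls
below 10% — configurable — of the largest improvement) and a boundary
warning when the optimum sits at the top of the range.  Ks whose cells all
failed are excluded with a warning.  The k-means sensitivity analysis
centres/scales the item codes, keeps principal components to ≥80%
cumulative variance, runs k-means with 25 seeded restarts and reports the
adjusted Rand index against the LCA modal classes.

## 3-step validation

Class membership is taken as the modal assignment (no BCH/ML correction
for classification error — a documented extension point; at the
calibrated profile's separation, modal accuracy is ≈97%, so the
attenuation from classification error is small).

Covariates: age (years, unstandardised), sex, LGBTIQ, NEET, region
(metropolitan/regional, derived from site), primary diagnosis, clinical
stage (0–1a / 1b / 2–4, reference 0–1a) and the symptom totals PHQ-9
(0–27), GAD-7 (0–21), SIQ-JR (0–90), PSQI (0–21).  Symptom totals are
standardised (centred, unit s.d.) with statistics shared across imputed
copies; fixed external s.d.s (e.g. published whole-cohort values) can be
supplied instead.  Dummies are never standardised.

Missing covariates are multiply imputed by chained equations
(`m = 20` copies, 10 sweeps, seeded): predictive-mean matching (5 donors)
for continuous, logistic draws for binary, multinomial-logistic draws for
categorical variables, with the assigned class included as a predictor so
the imputation model is congenial with the analysis model.  The per-
variable conditional fits use scikit-learn's linear/logistic regressions.

The multinomial logit is fitted by Newton–Raphson with step halving;
Wald covariances come from the inverse observed information.  Suspected
separation (diverging coefficients or non-convergence) triggers one
refit with a ridge penalty of 1e-4 on non-intercept terms — a documented
approximation whose covariance is the penalised-information inverse.
Rank-deficient designs are rejected with the aliased columns named (QR
with column pivoting).  The implementation is cross-checked against
statsmodels MNLogit in the test suite and reduces exactly (1e-6) to the
2×2 odds ratio in the binary case.

Rubin's rules pool the per-imputation estimates: pooled estimate = mean,
total variance `W̄ + (1 + 1/m) B`, Rubin degrees of freedom
`(m−1)(1 + W̄/((1+1/m)B))²` (infinite when B = 0, recovering single-fit
inference); CIs are formed on the log scale with the t/normal quantile and
exponentiated into RRRs.  Model 1 uses demographics + diagnosis + staging;
model 2 adds the four symptom totals (kept separate because diagnosed
severity and self-reported symptoms overlap).  Prediction accuracy is the
in-sample modal-agreement share, averaged over imputations.

## Synthetic cohort: what it emulates, and what it does not

The generator draws, per person: a latent class from the prevalence
vector; items conditionally independent given class; a site
(class-conditional probabilities, so regional/metropolitan composition can
differ by class); covariates from class-conditional families
(normal / Bernoulli / categorical, with optional clipping and integer
rounding); then item-level missingness on exactly the configured number of
rows (default 40, with 1–3 missing items per affected row) and
missing-completely-at-random covariate holes at per-variable rates taken
from the motivating cohort's reported missing counts (42 LGBTIQ, 32 NEET,
53 diagnosis, 31 staging, 4 PHQ-9, 6 GAD-7, 6 SIQ-JR, 48 PSQI, scaled by
N).  A single seeded generator stream drives everything, so identical
configurations give byte-identical cohorts.

The packaged `aqol_paper_profile` (N = 1107, prevalences 0.24/0.31/0.25/
0.20, five sites) is calibrated once, by `analysis/00_calibrate_profile.py`:
item severities are binomial-shaped category distributions whose per-class
levels are solved exactly — via the closed-form expected utility, which
factorises over dimensions under conditional independence — so the class
mean utilities equal 0.87 / 0.59 / 0.54 / 0.25; covariate parameters
encode the reported class summaries (SIQ-JR medians 4 vs 40, ~65% female,
~63% metropolitan, symptom s.d.s near 6.6/5.7/20.3/3.8, staging
composition implying a severe-vs-no/mild full-threshold RRR near 14).

What passing tests on this cohort *do not* show about real data: the
generator satisfies the LCA assumption (conditional independence within
class) by construction, so it cannot probe robustness to local
dependence; covariate missingness is MCAR, so it cannot probe imputation
under informative missingness; continuous covariates are (clipped,
rounded) normals with class-equal variances; and item distributions are
unimodal binomial shapes rather than the irregular margins real
questionnaires produce.  Results on this cohort certify the *machinery* —
estimators, selection, pooling — at realistic size and noise, not the
substantive findings for any clinical population.

## Problem sizes and runtime choices

The full-scale checks run the three CV schemes over K = 1..6 with 20
restarts at N = 1067 (≈100 (K, fold) fits), the class-number recovery
study at N = 1500 with 10 replicate seeds per generating K ∈ {1..4} using
split-half CV with 10 restarts, polychoric consistency at n = 50,000, and
the 3-step validation with m = 20 imputations.  These sizes were chosen so
the whole verification battery completes in a few minutes on one core
while keeping every tolerance at its stated value; the EM is vectorised
(one-hot response encoding, BLAS matmuls) specifically to make
CV-at-scale routine.

## Degenerate inputs and tie-breaks (summary)

* Empty classes in the M step: warning, row renormalised through the floor.
* Zero-probability observed cells: −∞ log-likelihood with a structured
  warning naming (class, item, category).
* Modal ties: lowest class index.
* MDS: negative eigenvalues truncated with warning; axis signs fixed.
* Thresholds: zero-margin categories collapse; single-category items error.
* Standardisation: zero s.d. errors, naming the variable; re-standardising
  an already-standardised variable is a no-op.
* Complete-case filter dropping everything: error, not an empty table.

## Known limitations

Modal 3-step regression is attenuated by classification error (no
BCH/ML correction); the utility surrogate is not the licensed adolescent
algorithm and absolute utility levels depend on its weights; selection
among CV indices matters near the decision boundary (held-out BIC is
conservative); the generator's conditional-independence and MCAR
assumptions are idealisations; and standard errors for π and ρ are not
computed (the validation interest is in the RRRs, which carry Wald/Rubin
uncertainty).
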