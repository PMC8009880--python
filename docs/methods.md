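# Methods

This note documents the statistical models and procedures implemented in
`neostrat`, the assumptions behind the synthetic cohort generator, the
numerical choices that matter, and the limitations a user should know
before trusting results on real data.

## Nutrition encoding

Curation reduces each infant's stay to a six-vector of proportions: the
number of complete days on which a component was given, divided by the
number of retained complete days. Length of stay is reported separately as
the span between the first and last day in care (`max − min`), so an
uninterrupted stay of span S contributes S+1 daily records and an encoding
denominator of S+1. When days are dropped for missingness the denominator
shrinks with the numerator, keeping every entry in [0, 1] by construction;
dividing instead by the raw span is available via
`encode_proportions(..., denominator="los")` for sensitivity analyses, with
the caveat that entries may then exceed 1 on complete stays.

Merging of same-day duplicate records (created when an infant transfers
between units) takes the union of non-missing events — the logical OR for
binary fields, the maximum for weights — and is idempotent. Episodic
constants are resolved by last-observation-carried-forward over episodes
ordered by admission time; ties at identical admission times resolve to the
last row in input order and are logged.

## The Dirichlet-process Gaussian mixture

The stratification model is a truncated stick-breaking DP mixture of full-
covariance Gaussians fitted by coordinate-ascent variational inference
(CAVI). Variational factors are Beta posteriors over stick fractions and
Normal–Wishart posteriors over component means and precisions. Priors
follow the empirical-Bayes convention: the mean prior sits at the dataset
mean (precision scale β₀ = 1), the Wishart prior scale at the dataset
covariance with ν₀ = d degrees of freedom — so a component with little data
reverts to a broad, dataset-shaped Gaussian.

Parameters that matter:

| parameter | default | meaning |
|---|---|---|
| `weight_concentration` | 1e-5 | DP concentration α; small values prefer few, uneven clusters. The final stratification is insensitive across α ∈ [1e-5, 1e5] (property-tested). |
| `tol` | 1e-3 | stop when the ELBO improves by less than this (total, not per-row). |
| `truncation` | 60 | stick-breaking truncation; only needs to exceed the number of clusters the data support. |
| `reg_covar` | 1e-6 | ridge on scale matrices; guards degenerate dimensions. |
| `n_init` | 1 | restarts; run-to-run variation is itself a study object, so it is not suppressed by default. |

**Initialisation.** Components are anchored at randomly chosen data points
and responsibilities come from one E-step under the broad data covariance
("random parameter values"). Near-uniform random responsibilities are *not*
used: they leave every component at the grand mean, where the sparse stick
prior (E[log(1−v)] ≈ ψ(α) ≈ −10⁵ for an emptied stick) kills all components
but one before they can differentiate — well-separated clusters then
collapse into a single Gaussian.

**ELBO.** The trace records the collapsed ELBO — responsibility entropy
plus the log-normalisers of the Beta and Normal–Wishart posteriors — which
is exact up to an additive constant at each CAVI step and non-decreasing
(tested to 1e-8). Density evaluation and sampling use plug-in posterior
parameters (means m_k, covariances Ψ_k/ν_k, normalised stick means); the
full Student-t predictive is deliberately out of scope, but parameter draws
from the variational posterior are available via `posterior_draw` for
uncertainty-aware replication.

Hard assignment takes the arg-max responsibility, ties to the lowest
component index. `stick_weights_` keeps the raw truncated stick masses with
the remainder accounted separately; `weights_` is the normalised version
used for assignment and sampling.

## Reproducibility protocol

The clustering F-measure is pinned to the class-weighted best-match form:
with contingency counts n_ij, per-pair precision n_ij/n_·j, recall
n_ij/n_i·, F(i,j) their harmonic mean, and
F_total = Σ_i (n_i·/n)·max_j F(i,j). It is 1 exactly for identical
partitions up to relabelling, and is verified in tests against a
brute-force enumeration oracle.

Run-to-run agreement pairs independently seeded fits disjointly (seeded
shuffle; one of each pair arbitrarily treated as ground truth). The
split-cohort protocol partitions by birth-year parity (2018 excluded as a
half-year), refits per sub-cohort and cross-assigns. Matched cluster pairs
(greedy matching by per-pair F, descending cluster size) are compared
variable-by-variable with Mann–Whitney U (continuous/ordinal) and Fisher's
exact test (binary), Bonferroni-corrected over the total test count.

**Posterior predictive check.** The PPC draws replicate datasets of the
held-out size from the fitted generative model and reports
p = P(statistic(replicate) ≥ statistic(held-out)), ties upward, for the
mean, variance, or log-likelihood statistic. Two properties deserve
emphasis. First, for genuinely held-out data and an adequately fitted
model the p-value is approximately *uniform* over repeated experiments —
near-0.5 values indicate adequacy, but a single p of 0.15 is not evidence
of misfit. Calibration is therefore asserted on the *mean* p over repeated
experiments. Second, the total-log-likelihood statistic sharpens with
held-out size (√n_holdout) while the small systematic covariance inflation
induced by the dataset-covariance prior decays as 1/n_train; the default
calibration protocol (train 3000, hold out 150) keeps the check in the
regime where the bias is negligible. Checking the training data itself, or
drawing replicate parameters from the mean-field posterior, both bias p
low, because the entropy of the plug-in parameters responds first-order to
covariance inflation; these variants were evaluated and rejected.

On curated cohort data (as opposed to model-family draws) the likelihood
PPC is an honest *misfit detector*: proportion-of-days data are bounded and
day-count-discretised, which a Gaussian mixture reproduces only
approximately, and large held-out sets will flag this.

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions.
Three default archetypes (weights 0.5/0.3/0.2) mimic common practice:
formula/maternal-milk trade-off (with a −0.4 MM–FM correlation),
maternal-milk-dominant with fortifier, and parenteral-intensive (lower
gestational age, elevated mortality, NEC and BPD risk). Within-archetype
sd is 0.05 with means kept ≥ 0.12 from the boundaries so that clipping
draws to [0, 1] leaves under 1% of mass at exact bounds — keeping the
planted structure genuinely three clusters. Day-counts are the clipped
draws rounded against the stay length; day sequences are realised with
component-specific exponential timeline weights (PN/GE front-loaded, FM and
BMF ramping up), so normalised-stay timelines are non-trivial.

Stays are discretised log-normal with median 49 days at the median
gestational age (29 weeks) and a −0.15/week GA gradient; deaths truncate
stays to a quarter. Admission covariates come from simple parametric
families (GA from a fixed very-preterm stratum distribution over 22–31
weeks; birth-weight z-score standard normal around −0.16; Apgar scores as
clipped rounded normals; four regions at 30/27/20/23%). Outcomes are
generated with stated effect sizes — continuous as baseline + covariate
effects + archetype effect + Gaussian noise, binary through logistic models
— and then *realised into the raw tables*: death as a discharge
destination, BPD as a respiratory-support flag on the 36-week
postmenstrual-age day, weight trajectories interpolating birth to the
planted 36-week z-score through an invertible LMS reference.
MM-at-discharge is emergent from the realised day sequences rather than
planted, avoiding inconsistency with the day-counts. Transfer infants (35%)
get a second episode and a split transfer-day record to exercise merging
and LOCF.

What the generator does **not** emulate: zero-inflation of real
proportion-of-days data (real cohorts have large point masses at exactly 0
and 1, e.g. infants who never receive donor milk); within-infant temporal
autocorrelation beyond the timeline-weight profiles; ventilation and
multi-unit trajectories; calibration of covariate distributions beyond the
medians used. Passing tests therefore demonstrate correctness of the
machinery and recoverability under Gaussian-cluster conditions — not that a
real registry has three clusters, nor that the Gaussian mixture's PPC would
endorse real data.

The LMS reference shipped for simulations is synthetic (smooth exponential
median curves, constant L = 0.8, S = 0.11); real analyses must supply a
published growth reference as a CSV keyed by sex, gestational age and
postnatal day.

## Admission grouping

Cluster profiles are mean admission/outcome variables per cluster,
standardised across clusters with the sample (n−1) standard deviation;
zero-variance variables are dropped with a warning. Ward linkage on
Euclidean distance over the admission z-scores gives the merge tree; a 2-D
PCA of the same matrix gives the projection and per-variable loadings.
Flat admission groups come from an explicit cut (count or height), lettered
in dendrogram display order — an explicit parameter replaces visual
inspection so results are reproducible. Grouping is restricted by default
to the most populated clusters covering 95% of infants.

## Deconfounder

For a contrast between clusters C₁ and C₀ on an outcome, eligible infants
(alive at discharge, in care at 36 weeks postmenstrual age, complete
records) contribute a design of mean-centred covariates — birth-weight
z-score, antenatal steroids, Apgar 1, IMD decile, smoking, sex, gestational
age, and region dummies against the London-like reference; the late Apgar
scores and resuscitation are excluded as collinear. A probabilistic PCA
factor model with three latents is fitted to 80% of the rows (closed-form
ML: loadings from the top-k eigenpairs, isotropic noise = mean discarded
eigenvalue) and checked by a likelihood PPC on the 20% hold-out; its
posterior latent means join the outcome regression (OLS for continuous,
logistic for binary, Wald 95% CIs, adjusted r² / McFadden pseudo-r²).
Binary and ordinal covariates enter the factor model as centred numerics —
a documented approximation.

**The collinearity caveat.** PPCA posterior latent means are exact affine
functions of the covariates they are fitted on. A regression containing
both the full covariate set and the latents therefore has a rank-deficient
design; the OLS path resolves it by pseudo-inverse and the treatment
coefficient is unaffected (the regression span is unchanged), but the
individual covariate and latent coefficients share their span arbitrarily
and should not be over-interpreted. The latents carry *independent*
adjustment value exactly when the outcome model does not span all
factor-model inputs — which is how the bias-reduction property is
demonstrated: with a planted latent confounder driving ten covariate
proxies, the treatment, and the outcome, the regression on treatment +
latents shows an order-of-magnitude smaller treatment bias than the
regression on treatment alone (median over 100 replicates). Logistic fits
with perfect separation are flagged and refitted with a small L2 ridge
(Newton iterations, Wald intervals from the penalised Hessian).

## Numerical conventions and degenerate inputs

* F-measure and matching are deterministic; matching order is descending
  cluster size, ties to the lower cluster index.
* Responsibilities rows sum to 1 within 1e-12 (log-sum-exp); covariance
  operations go through Cholesky factors.
* An all-identical-day infant encodes to a vertex of [0,1]⁶; zero-denominator
  infants (no complete days) are excluded and counted.
* `cut_admission_groups` requires exactly one of a group count or a height;
  k beyond the leaf count errors.
* PPCA permits k equal to the matrix rank (zero-noise analytic limit) and
  rejects k beyond it; `score_samples` requires positive noise.
* Every stochastic routine takes an explicit seed; identical configuration
  and seed reproduce byte-identical artifacts.

## Problem sizes

The test suite and the acceptance script run their simulation studies at
explicit sizes chosen to make each check statistically meaningful at
interactive cost: 3000-infant cohorts for stratification studies (five fits at
truncation 60 in ~15 s), 20-fit agreement studies at truncation 20,
PPC calibration at train 3000 / hold-out 150 with 100 replicates, and
deconfounder simulations at n = 700 per design with 100–500 replicates.
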